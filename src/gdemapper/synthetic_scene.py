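"""Synthetic dryland landscapes with groundwater-dependent "islands".

The generator emulates the statistical structure the mapping analysis
relies on: patches of groundwater-dependent vegetation that stay green
and moist through the dry season, run a few degrees cooler than their
surroundings, transpire more water than falls as precipitation, and sit
over shallow water tables — embedded in a xeric matrix that senesces in
the dry season, with clouds, quality dropouts and sensor noise layered on
top.  Nothing here claims radiometric realism; the point is a landscape
in which every downstream stage (masking, feature engineering,
classification, validation, storage trends) is exercised end to end with
known ground truth.

A single ``contrast`` knob scales every GDE-vs-matrix difference; at
contrast 0 the GDE pixels are statistically identical to the matrix in
every predictor, which provides the chance-level control for classifier
calibration checks.

Each stochastic component (terrain, patches, land cover, reflectance,
clouds, thermal noise, climate forcing, storage) draws from its own
stream spawned from the master seed, so adding one component never
perturbs the others.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import extent_mask as em
from .predictors import QA_CODES, SceneObservation
from .raster_core import RasterGrid

DEG_PER_ARCSEC = 1.0 / 3600.0

#: degC of GDE cooling per unit contrast (dry season).
DELTA_T_PER_CONTRAST = 2.0

#: matrix annual transpiration/precipitation ratio, and its increase per
#: unit contrast on GDE pixels (contrast 2 -> ratio 1.25 > 1).
ETAP_MATRIX = 0.65
ETAP_SLOPE = 0.30

REGION_NAMES = ("NW", "NE", "SW", "SE")


class SceneError(ValueError):
    """Invalid scenario configuration or exhausted sampling stratum."""


@dataclass
class ScenarioConfig:
    """Knobs of a simulated landscape.

    Defaults follow the observational design of the satellite analysis:
    six years of imagery, ~30 m (1 arcsecond) pixels, dry-season windows
    by hemisphere.  ``contrast`` is the dimensionless GDE-vs-matrix
    signal separation: reflectance shifts of ``contrast * noise_sd``,
    cooling of ``contrast * 2`` degC, and proportional shifts in the
    transpiration ratio and topographic position.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = DEG_PER_ARCSEC
    origin_lon: float = -116.0
    origin_lat: float = 38.0
    n_years: int = 6
    start_year: int = 2015
    obs_per_season: int = 3
    gde_fraction: float = 0.10
    patch_geometry: dict = field(default_factory=lambda: {
        "riparian_corridor": 0.4, "spring_disc": 0.2, "phreatophyte_patch": 0.4,
    })
    contrast: float = 2.0
    cloud_prob: float = 0.05
    lst_uncert_sd: float = 1.5
    noise_sd: float = 0.05
    dtg_range: tuple[float, float] = (0.0, 60.0)
    seed: int = 0
    #: optional per-region contrast multipliers (quadrant name -> factor),
    #: e.g. {"SE": 0.0} plants a zero-signal region for extrapolation tests
    region_contrast: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.gde_fraction <= 1.0:
            raise SceneError(f"gde_fraction must be in [0,1], got {self.gde_fraction}")
        if self.contrast < 0:
            raise SceneError(f"contrast must be >= 0, got {self.contrast}")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise SceneError(f"cloud_prob must be in [0,1], got {self.cloud_prob}")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))


@dataclass
class StorageSeries:
    """Monthly storage anomalies, cm equivalent water thickness.

    ``tws`` is the exact sum of the planted groundwater signal and the
    three subtracted components, so the decomposition identity holds by
    construction; the planted groundwater series and its linear trend are
    kept in ``metadata`` for recovery tests.
    """

    dates: pd.DatetimeIndex
    tws: np.ndarray
    sm: np.ndarray
    swe: np.ndarray
    canopy: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "tws": self.tws, "sm": self.sm,
             "swe": self.swe, "canopy": self.canopy}
        )


@dataclass
class SceneBundle:
    """A simulated landscape plus everything the pipeline consumes."""

    config: ScenarioConfig
    dem: RasterGrid
    dtg: RasterGrid
    landcover: RasterGrid
    climate_class: RasterGrid
    truth: RasterGrid
    regions: RasterGrid          # integer codes into region_names
    region_names: tuple[str, ...]
    observations: list[SceneObservation]
    precip: list[tuple[dt.date, RasterGrid]]
    transp: list[tuple[dt.date, RasterGrid]]
    storage: StorageSeries
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to zero mean, unit variance."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / (sd if sd > 0 else 1.0)


def _grid(cfg: ScenarioConfig, values: np.ndarray, name: str) -> RasterGrid:
    return RasterGrid(values, origin_lon=cfg.origin_lon, origin_lat=cfg.origin_lat,
                      cell_size=cfg.cell_size, layer_name=name)


def _dry_months(cfg: ScenarioConfig) -> tuple[int, int, int]:
    return (7, 8, 9) if cfg.origin_lat >= 0 else (1, 2, 3)


def _wet_months(cfg: ScenarioConfig) -> tuple[int, int, int]:
    return (1, 2, 3) if cfg.origin_lat >= 0 else (7, 8, 9)


def _region_codes(cfg: ScenarioConfig) -> np.ndarray:
    """Quadrant partition: NW=0, NE=1, SW=2, SE=3."""
    rows = np.arange(cfg.n_rows)[:, None] >= cfg.n_rows // 2  # south half
    cols = np.arange(cfg.n_cols)[None, :] >= cfg.n_cols // 2  # east half
    return (rows * 2 + cols).astype(float) * np.ones((cfg.n_rows, cfg.n_cols))


def _contrast_map(cfg: ScenarioConfig, regions: np.ndarray) -> np.ndarray:
    c = np.full(regions.shape, cfg.contrast)
    for name, factor in cfg.region_contrast.items():
        code = REGION_NAMES.index(name)
        c[regions == code] = cfg.contrast * factor
    return c


# ---------------------------------------------------------------------------
# truth-patch geometry
# ---------------------------------------------------------------------------

def _corridor_pixels(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Random-walk polyline across the scene, dilated to 1-3 px width."""
    nr, nc = shape
    mask = np.zeros(shape, bool)
    # start on a random edge, walk with momentum until leaving the scene
    r = float(rng.integers(0, nr))
    c = 0.0 if rng.random() < 0.5 else float(nc - 1)
    heading = 0.0 if c == 0.0 else np.pi  # eastward / westward
    steps = 0
    while 0 <= r < nr and 0 <= c < nc and steps < 4 * (nr + nc):
        mask[int(r), int(c)] = True
        heading += rng.normal(0.0, 0.25)
        r += np.sin(heading)
        c += np.cos(heading)
        steps += 1
    width = int(rng.integers(1, 4))  # 1-3 px
    if width > 1:
        mask = ndimage.binary_dilation(mask, iterations=width - 1)
    return mask


def _spring_pixels(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    nr, nc = shape
    mask = np.zeros(shape, bool)
    radius = float(rng.integers(1, 3))  # 1-2 px
    cr, cc = rng.integers(0, nr), rng.integers(0, nc)
    rr, cc_ = np.ogrid[:nr, :nc]
    mask[(rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2] = True
    return mask


def _blob_pixels(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Smoothed-noise threshold blob around a random center (irregular patch)."""
    nr, nc = shape
    cr, cc = rng.integers(0, nr), rng.integers(0, nc)
    a = float(rng.uniform(3, 9))
    b = float(rng.uniform(3, 9))
    rr, cc_ = np.ogrid[:nr, :nc]
    d2 = ((rr - cr) / a) ** 2 + ((cc_ - cc) / b) ** 2
    wobble = ndimage.gaussian_filter(rng.standard_normal(shape), 2.0, mode="reflect")
    sd = wobble.std()
    wobble = wobble / (sd if sd > 0 else 1.0)
    return (d2 + 0.4 * wobble) < 1.0


_PATCH_BUILDERS = {
    "riparian_corridor": _corridor_pixels,
    "spring_disc": _spring_pixels,
    "phreatophyte_patch": _blob_pixels,
}


def _build_truth(cfg: ScenarioConfig, rng: np.random.Generator,
                 forbidden: np.ndarray) -> np.ndarray:
    """Place patches until the target GDE pixel count is met (within a pixel).

    A patch that would overshoot the target is trimmed to a random subset
    of the pixels still needed, so the realised fraction tracks the
    requested one closely.
    """
    shape = (cfg.n_rows, cfg.n_cols)
    target = int(round(cfg.gde_fraction * cfg.n_rows * cfg.n_cols))
    truth = np.zeros(shape, bool)
    if target < 1:
        if cfg.gde_fraction > 0:
            warnings.warn("gde_fraction yields < 1 pixel; truth mask is empty")
        return truth
    kinds = list(cfg.patch_geometry)
    weights = np.array([cfg.patch_geometry[k] for k in kinds], float)
    weights = weights / weights.sum()
    attempts = 0
    while truth.sum() < target and attempts < 10000:
        attempts += 1
        kind = kinds[rng.choice(len(kinds), p=weights)]
        new = _PATCH_BUILDERS[kind](rng, shape) & ~forbidden & ~truth
        n_new = int(new.sum())
        if n_new == 0:
            continue
        need = target - int(truth.sum())
        if n_new > need:
            idx = np.flatnonzero(new.ravel())
            keep = rng.choice(idx, size=need, replace=False)
            new = np.zeros(shape, bool)
            new.ravel()[keep] = True
        truth |= new
    return truth


# ---------------------------------------------------------------------------
# storage time series
# ---------------------------------------------------------------------------

def generate_storage_series(
    trend: float = -0.5,
    seasonal_amp: float = 2.0,
    noise_sd: float = 1.0,
    n_months: int = 241,
    seed: int = 0,
    start: str = "2002-04-01",
) -> StorageSeries:
    """Monthly storage anomalies with a planted groundwater trend.

    The groundwater component is ``trend * t + seasonal sinusoid + white
    noise`` (t in decimal years); soil moisture, snow and canopy are
    independent seasonal-plus-noise series with zero trend, and the
    terrestrial total is their exact sum.  The default 241 months span
    April 2002-April 2022, the window used for trend reporting.
    """
    if n_months < 24:
        raise SceneError(f"n_months must be >= 24, got {n_months}")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n_months, freq="MS")
    t = np.arange(n_months) / 12.0
    phase = 2.0 * np.pi * t

    gws = trend * t + seasonal_amp * np.sin(phase) + (
        rng.standard_normal(n_months) * noise_sd if noise_sd > 0 else 0.0
    )
    sm = 0.8 * seasonal_amp * np.sin(phase + 0.6) + (
        rng.standard_normal(n_months) * 0.5 * noise_sd if noise_sd > 0 else 0.0
    )
    swe = np.maximum(0.4 * seasonal_amp * np.sin(phase + np.pi / 2), 0.0) + (
        rng.standard_normal(n_months) * 0.2 * noise_sd if noise_sd > 0 else 0.0
    )
    canopy = 0.1 * seasonal_amp * np.sin(phase + 1.2) + (
        rng.standard_normal(n_months) * 0.1 * noise_sd if noise_sd > 0 else 0.0
    )
    tws = gws + sm + swe + canopy
    return StorageSeries(
        dates=dates, tws=tws, sm=sm, swe=swe, canopy=canopy,
        metadata={"true_trend_cm_per_yr": float(trend), "gws_true": gws},
    )


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def generate_scene(config: ScenarioConfig) -> SceneBundle:
    """Build a complete simulated landscape; deterministic for a fixed seed."""
    cfg = config
    shape = (cfg.n_rows, cfg.n_cols)
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_terrain, rng_patch, rng_cover, rng_refl, rng_cloud, rng_lst, \
        rng_forcing, rng_storage = (np.random.default_rng(s) for s in streams)

    # --- land cover: coherent matrix plus special blocks with known counts
    cover_field = _smooth_field(rng_cover, shape, sigma=6.0)
    landcover = np.where(
        cover_field > 0.6, em.LANDCOVER_CODES["grassland"],
        np.where(cover_field < -0.8, em.LANDCOVER_CODES["barren"],
                 em.LANDCOVER_CODES["shrubland"]),
    ).astype(float)

    def _place_block(code: int, r0: int, c0: int, h: int, w: int) -> int:
        landcover[r0 : r0 + h, c0 : c0 + w] = code
        return h * w

    nr, nc = shape
    n_crop = _place_block(em.LANDCOVER_CODES["cropland"], 2, 2, min(10, nr - 4), min(20, nc - 4))
    n_built = _place_block(em.LANDCOVER_CODES["built"], 2, min(30, nc - 14), min(10, nr - 4), min(10, nc - 4))
    n_water = _place_block(em.LANDCOVER_CODES["water"], min(20, nr - 8), 2, min(6, nr - 4), min(6, nc - 4))
    water = landcover == em.LANDCOVER_CODES["water"]

    # --- climate: dryland everywhere but one humid block in the far corner
    climate = np.full(shape, float(em.CLIMATE_CODES["B"]))
    hsz = min(8, nr - 2, nc - 2)
    climate[nr - hsz :, nc - hsz :] = em.CLIMATE_CODES["humid"]
    n_humid = hsz * hsz

    # --- truth mask avoids masked cover and the humid corner
    forbidden = np.isin(
        landcover,
        [em.LANDCOVER_CODES[k] for k in ("cropland", "built", "water")],
    ) | (climate != em.CLIMATE_CODES["B"])
    truth = _build_truth(cfg, rng_patch, forbidden)
    # keep barren for the barren-point stratum: truth pixels are vegetated
    landcover[truth & (landcover == em.LANDCOVER_CODES["barren"])] = \
        em.LANDCOVER_CODES["shrubland"]

    regions = _region_codes(cfg)
    cmap = _contrast_map(cfg, regions)
    gde_sig_core = truth * cmap  # per-pixel signal strength, 0 on the matrix

    # --- terrain: rolling surface, carved down along GDE features so the
    #     topographic-wetness signal points at them (scaled by contrast)
    dem = (
        1500.0
        + 45.0 * _smooth_field(rng_terrain, shape, sigma=18.0)
        + 12.0 * _smooth_field(rng_terrain, shape, sigma=5.0)
        - 6.0 * ndimage.gaussian_filter((truth * cmap).astype(float), 2.0, mode="reflect")
    )

    # --- depth to groundwater: smooth regional field; truth pixels shallow
    lo, hi = cfg.dtg_range
    dtg_field = _smooth_field(rng_terrain, shape, sigma=12.0)
    dtg = lo + (hi - lo) * (1.0 / (1.0 + np.exp(-1.2 * dtg_field)))
    shallow = rng_terrain.uniform(0.5, 12.0, size=shape)
    dtg = np.where(truth, np.minimum(shallow, em.DTG_MAX_DEFAULT - 0.5), dtg)
    # source-data artefacts: gaps around water plus scattered isolated holes
    near_water = ndimage.binary_dilation(water, iterations=2)
    dtg = np.where(near_water, np.nan, dtg)
    holes = rng_terrain.random(shape) < 0.003
    dtg = np.where(holes & ~truth, np.nan, dtg)
    dtg_vals = np.where(np.isnan(dtg), -9999.0, dtg)

    # --- observations -------------------------------------------------------
    soil_bright = 0.02 * _smooth_field(rng_refl, shape, sigma=10.0)
    lst_topo = 1.5 * _smooth_field(rng_lst, shape, sigma=12.0)
    year_anom = rng_refl.normal(0.0, 0.03, size=cfg.n_years)  # matrix interannual wobble
    # persistent pixel-scale heterogeneity (soil/canopy texture): identical in
    # every observation, so temporal compositing cannot average it away —
    # reflectance indices stay noisier separators than the ETaP and thermal
    # signatures, which are the distinctive groundwater signals
    band_pers = {name: 0.8 * cfg.noise_sd * rng_refl.standard_normal(shape)
                 for name in ("red", "green", "nir", "swir1")}
    lst_pers = 0.5 * rng_lst.standard_normal(shape)

    dry_doy = np.linspace(15, 75, cfg.obs_per_season)  # spread inside the window
    observations: list[SceneObservation] = []
    for yi, year in enumerate(cfg.years):
        for season, months in (("dry", _dry_months(cfg)), ("wet", _wet_months(cfg))):
            base_dates = [
                dt.date(year, months[int(k) // 31], 1) + dt.timedelta(days=int(k) % 28)
                for k in dry_doy
            ]
            for date in base_dates:
                if season == "dry":
                    red = 0.28 + soil_bright - 0.010 * gde_sig_core
                    green = 0.24 + soil_bright + 0.004 * gde_sig_core
                    nir = 0.30 + soil_bright + year_anom[yi] + cfg.noise_sd * gde_sig_core
                    swir1 = 0.42 + soil_bright - cfg.noise_sd * gde_sig_core
                    lst = 36.0 + lst_topo - DELTA_T_PER_CONTRAST * gde_sig_core
                else:
                    # wet season: matrix greens up, GDE advantage vanishes
                    red = 0.20 + soil_bright
                    green = 0.22 + soil_bright
                    nir = 0.38 + soil_bright + year_anom[yi]
                    swir1 = 0.30 + soil_bright
                    lst = 22.0 + lst_topo
                bands = {}
                for name, base in (("red", red), ("green", green),
                                   ("nir", nir), ("swir1", swir1)):
                    noisy = base + band_pers[name] + rng_refl.normal(0.0, cfg.noise_sd, shape)
                    bands[name] = np.clip(noisy, 0.0, 1.0)
                # open water: dark in NIR/SWIR, bright-ish in green, cool
                bands["nir"][water] = np.clip(0.04 + 0.01 * rng_refl.standard_normal(int(water.sum())), 0, 1)
                bands["swir1"][water] = 0.03
                bands["green"][water] = 0.12
                lst = lst.copy()
                lst[water] = 24.0
                lst = lst + lst_pers + rng_lst.normal(0.0, 1.0, shape)
                lst_uncert = np.abs(rng_lst.normal(2.0, cfg.lst_uncert_sd, shape))

                qa = np.full(shape, float(QA_CODES["clear"]))
                # spatially coherent clouds at roughly cloud_prob coverage
                cl_field = _smooth_field(rng_cloud, shape, sigma=8.0)
                if cfg.cloud_prob > 0:
                    cut = np.quantile(cl_field, 1.0 - cfg.cloud_prob)
                    cloudy = cl_field > cut
                    qa[cloudy] = QA_CODES["cloud"]
                    shadow = ndimage.binary_dilation(cloudy, iterations=1) & ~cloudy
                    qa[shadow & (rng_cloud.random(shape) < 0.5)] = QA_CODES["shadow"]
                # occasional write-off scene well above the 20% screening rule
                if rng_cloud.random() < 0.06:
                    cut = np.quantile(cl_field, 0.65)
                    qa[cl_field > cut] = QA_CODES["cloud"]
                cloud_frac = float(np.mean(qa != QA_CODES["clear"]))

                observations.append(SceneObservation(
                    date=date,
                    red=_grid(cfg, bands["red"], "red"),
                    green=_grid(cfg, bands["green"], "green"),
                    nir=_grid(cfg, bands["nir"], "nir"),
                    swir1=_grid(cfg, bands["swir1"], "swir1"),
                    lst=_grid(cfg, lst, "lst"),
                    lst_uncert=_grid(cfg, lst_uncert, "lst_uncert"),
                    qa=_grid(cfg, qa, "qa"),
                    scene_cloud_fraction=cloud_frac,
                ))

    # --- monthly climate forcing (mm): wet-season peaked precipitation;
    #     transpiration set so ETaP separates GDE from matrix by contrast
    precip_total = 320.0 * (1.0 + 0.15 * _smooth_field(rng_forcing, shape, sigma=15.0))
    wet = set(_wet_months(cfg))
    month_weight = {m: (0.20 if m in wet else 0.05) for m in range(1, 13)}
    wsum = sum(month_weight.values())
    etap_factor = ETAP_MATRIX + ETAP_SLOPE * gde_sig_core
    precip_series: list[tuple[dt.date, RasterGrid]] = []
    transp_series: list[tuple[dt.date, RasterGrid]] = []
    for year in cfg.years:
        yr_wob = 1.0 + rng_forcing.normal(0.0, 0.08)
        for m in range(1, 13):
            p = precip_total * month_weight[m] / wsum * yr_wob
            p = np.maximum(p + rng_forcing.normal(0.0, 1.0, shape), 0.0)
            tr = np.maximum(etap_factor * p + rng_forcing.normal(0.0, 0.5, shape), 0.0)
            date = dt.date(year, m, 15)
            precip_series.append((date, _grid(cfg, p, "precip")))
            transp_series.append((date, _grid(cfg, tr, "transp")))

    storage = generate_storage_series(seed=int(rng_storage.integers(2**31)))

    return SceneBundle(
        config=cfg,
        dem=_grid(cfg, dem, "dem"),
        dtg=_grid(cfg, dtg_vals, "dtg"),
        landcover=_grid(cfg, landcover, "landcover"),
        climate_class=_grid(cfg, climate, "climate_class"),
        truth=_grid(cfg, truth.astype(float), "truth"),
        regions=_grid(cfg, regions, "regions"),
        region_names=REGION_NAMES,
        observations=observations,
        precip=precip_series,
        transp=transp_series,
        storage=storage,
        metadata={
            "n_cropland_px": n_crop, "n_built_px": n_built,
            "n_water_px": n_water, "n_humid_px": n_humid,
            "n_truth_px": int(truth.sum()),
            "target_truth_px": int(round(cfg.gde_fraction * cfg.n_rows * cfg.n_cols)),
        },
    )


# ---------------------------------------------------------------------------
# point sampling
# ---------------------------------------------------------------------------

def scene_extent(bundle: SceneBundle) -> em.ExtentMasks:
    """The analysis extent of a bundle (climate x land cover x filled DTG)."""
    climate_ok = em.climate_mask(bundle.climate_class)
    landcover_ok = em.landcover_mask(bundle.landcover)
    w = em.water_mask(bundle.landcover)
    dtg_filled = em.fill_dtg(bundle.dtg, w)
    return em.build_extent(climate_ok, landcover_ok, dtg_filled)


def sample_points(
    bundle: SceneBundle,
    n_gde: int,
    n_nongde: int,
    n_barren: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw labelled training/validation points from a scene.

    GDE points come uniformly from truth pixels; non-GDE points from
    in-extent, non-truth, non-barren pixels; barren points (labelled
    NONGDE, after the barren-area sampling used for absence data) from
    barren land cover.  Points sit at pixel centers and carry a region
    tag from the scene's quadrant partition.
    """
    rng = np.random.default_rng(seed)
    extent = scene_extent(bundle).extent.values == 1.0
    truth = bundle.truth.values == 1.0
    barren = bundle.landcover.values == em.LANDCOVER_CODES["barren"]
    strata = {
        "GDE": (truth, "GDE", "truth_patch"),
        "NONGDE": (extent & ~truth & ~barren, "NONGDE", "matrix"),
        "BARREN": (barren & extent, "NONGDE", "barren_sample"),
    }
    wanted = {"GDE": n_gde, "NONGDE": n_nongde, "BARREN": n_barren}
    ref = bundle.truth
    lats = ref.row_lat_centers()
    lons = ref.col_lon_centers()
    frames = []
    for stratum, (mask, label, source) in strata.items():
        n = wanted[stratum]
        if n == 0:
            continue
        idx = np.flatnonzero(mask.ravel())
        if n > len(idx):
            raise SceneError(
                f"stratum {stratum!r} exhausted: requested {n}, available {len(idx)}"
            )
        pick = rng.choice(idx, size=n, replace=False)
        rows, cols = np.unravel_index(pick, mask.shape)
        frames.append(pd.DataFrame({
            "lon": lons[cols],
            "lat": lats[rows],
            "label": label,
            "source": source,
            "region": [bundle.region_names[int(bundle.regions.values[r, c])]
                       for r, c in zip(rows, cols)],
        }))
    if not frames:
        return pd.DataFrame(columns=["lon", "lat", "label", "source", "region"])
    return pd.concat(frames, ignore_index=True)
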