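"""The 11 predictor variables fed to the classifier.

Eight come from four spectral indices (NDVI, NDMI, NDWI, MSAVI), each
summarized as (i) the multi-year mean of annual dry-season averages and
(ii) the interannual coefficient of variation of those annual averages.
The dry season is 1 July-30 September in the northern hemisphere and
1 January-31 March in the southern (per-pixel by latitude sign; the
equator row counts as northern).  The remaining three are:

* ``etap`` — the mean over years of annual transpiration / precipitation
  ratios; values above 1 flag vegetation likely subsidised by groundwater;
* ``cti`` — the compound topographic index ln(contributing area / tan
  slope), high in convergent valley positions;
* ``lst_anom`` — the multi-scale land-surface-temperature spatial anomaly:
  a pixel's deviation from its neighbourhood mean at window sides of 270,
  2700 and 5400 m (9/91/181 pixels at 30 m), averaged across scales and
  then over dry-season observations and years.  Cool pixels (negative
  anomaly) are candidate groundwater-dependent ecosystems.

Observation screening drops whole scenes above 20% cloud cover, masks
cloud/shadow/snow pixels, and discards temperatures with uncertainty
above 5 degC.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .raster_core import RasterGrid, RasterError, require_coregistered

# QA vocabulary for observation pixels.
QA_CODES: dict[str, int] = {"clear": 0, "cloud": 1, "shadow": 2, "snow": 3}
QA_BAD = (QA_CODES["cloud"], QA_CODES["shadow"], QA_CODES["snow"])

SCENE_CLOUD_MAX = 0.20    # scenes strictly above this fraction are dropped
LST_UNCERT_MAX = 5.0      # degC; strictly-greater pixels are dropped
CV_MEAN_EPS = 1e-6        # |mean| below this -> CV undefined

INDEX_KINDS = ("NDVI", "NDMI", "NDWI", "MSAVI")

#: Canonical predictor layer order.
LAYER_ORDER = (
    "ndvi_mean", "ndvi_cv", "ndmi_mean", "ndmi_cv", "ndwi_mean", "ndwi_cv",
    "msavi_mean", "msavi_cv", "etap", "cti", "lst_anom",
)

#: LST anomaly window side lengths, metres, and the pixel size they assume.
LST_WINDOW_SIDES_M = (270.0, 2700.0, 5400.0)
LST_ASSUMED_PIXEL_M = 30.0


@contextmanager
def _quiet_nan():
    """Silence all-NaN-slice warnings from nan-aware reductions."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        with np.errstate(invalid="ignore", divide="ignore"):
            yield


@dataclass
class SceneObservation:
    """One dated acquisition: reflectance bands, thermal band and QA."""

    date: dt.date
    red: RasterGrid
    green: RasterGrid
    nir: RasterGrid
    swir1: RasterGrid
    lst: RasterGrid
    lst_uncert: RasterGrid
    qa: RasterGrid
    scene_cloud_fraction: float = 0.0

    def grids(self) -> tuple[RasterGrid, ...]:
        return (self.red, self.green, self.nir, self.swir1,
                self.lst, self.lst_uncert, self.qa)


@dataclass
class PredictorStack:
    """The 11 named, co-registered predictor layers in canonical order."""

    layers: dict[str, RasterGrid]

    def __post_init__(self) -> None:
        names = list(self.layers)
        missing = [n for n in LAYER_ORDER if n not in names]
        extra = [n for n in names if n not in LAYER_ORDER]
        if missing or extra:
            raise RasterError(
                f"predictor stack needs exactly the 11 canonical layers; "
                f"missing={missing}, extra={extra}"
            )
        self.layers = {n: self.layers[n] for n in LAYER_ORDER}
        require_coregistered(*self.layers.values())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    @property
    def grid(self) -> RasterGrid:
        """A reference grid carrying the stack's georeference."""
        return self.layers[LAYER_ORDER[0]]

    def as_array(self) -> np.ndarray:
        """(n_layers, rows, cols) array with NaN for nodata."""
        out = []
        for g in self.layers.values():
            out.append(np.where(g.valid_mask(), g.values, np.nan))
        return np.stack(out)

    def sample_at(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """(n_points, 11) predictor matrix at coordinates; NaN where nodata
        or out of bounds."""
        ref = self.grid
        row, col = ref.lonlat_to_rowcol(np.asarray(lon), np.asarray(lat))
        inside = (row >= 0) & (row < ref.n_rows) & (col >= 0) & (col < ref.n_cols)
        cube = self.as_array()
        X = np.full((len(row), len(LAYER_ORDER)), np.nan)
        X[inside] = cube[:, row[inside], col[inside]].T
        return X


def hemisphere_dry_months(lat: float) -> tuple[int, int, int]:
    """Dry-season months for a latitude; lat >= 0 uses the northern window."""
    return (7, 8, 9) if lat >= 0 else (1, 2, 3)


def is_dry_season(date: dt.date, lat: float) -> bool:
    return date.month in hemisphere_dry_months(lat)


# ---------------------------------------------------------------------------
# QA screening
# ---------------------------------------------------------------------------

def qa_screen(observations: Iterable[SceneObservation]) -> list[SceneObservation]:
    """Apply scene- and pixel-level quality rules.

    Scenes with cloud fraction strictly above 20% are dropped entirely.
    In retained scenes, reflectance pixels flagged cloud/shadow/snow
    become nodata, and LST pixels with uncertainty strictly above 5 degC
    become nodata.
    """
    out: list[SceneObservation] = []
    for obs in observations:
        if obs.scene_cloud_fraction > SCENE_CLOUD_MAX:
            continue
        bad_px = np.isin(obs.qa.values, QA_BAD)
        bands = {}
        for name in ("red", "green", "nir", "swir1"):
            g: RasterGrid = getattr(obs, name)
            bands[name] = g.with_values(np.where(bad_px, g.nodata, g.values))
        uncert_valid = obs.lst_uncert.valid_mask()
        too_uncertain = uncert_valid & (obs.lst_uncert.values > LST_UNCERT_MAX)
        lst = obs.lst.with_values(
            np.where(bad_px | too_uncertain, obs.lst.nodata, obs.lst.values)
        )
        out.append(replace(obs, lst=lst, **bands))
    return out


# ---------------------------------------------------------------------------
# spectral indices
# ---------------------------------------------------------------------------

def spectral_index(obs: SceneObservation, kind: str) -> RasterGrid:
    """Compute one of NDVI / NDMI / NDWI / MSAVI for an observation.

    NDVI = (NIR-Red)/(NIR+Red); NDMI = (NIR-SWIR1)/(NIR+SWIR1);
    NDWI = (Green-NIR)/(Green+NIR);
    MSAVI = (2 NIR + 1 - sqrt((2 NIR + 1)^2 - 8 (NIR - Red))) / 2.
    Zero denominators and negative radicands map to nodata.
    """
    kind = kind.upper()
    if kind not in INDEX_KINDS:
        raise RasterError(f"unknown index kind {kind!r}; expected one of {INDEX_KINDS}")
    nir, red, green, swir1 = obs.nir, obs.red, obs.green, obs.swir1
    if kind == "NDVI":
        a, b = nir, red
    elif kind == "NDMI":
        a, b = nir, swir1
    elif kind == "NDWI":
        a, b = green, nir
    else:  # MSAVI
        valid = nir.valid_mask() & red.valid_mask()
        n, r = nir.values, red.values
        radicand = (2.0 * n + 1.0) ** 2 - 8.0 * (n - r)
        ok = valid & (radicand >= 0)
        with np.errstate(invalid="ignore"):
            msavi = (2.0 * n + 1.0 - np.sqrt(np.where(ok, radicand, 0.0))) / 2.0
        return nir.with_values(
            np.where(ok, msavi, nir.nodata), layer_name="msavi"
        )
    valid = a.valid_mask() & b.valid_mask()
    denom = a.values + b.values
    ok = valid & (denom != 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(ok, (a.values - b.values) / np.where(ok, denom, 1.0), a.nodata)
    return a.with_values(idx, layer_name=kind.lower())


# ---------------------------------------------------------------------------
# dry-season temporal statistics
# ---------------------------------------------------------------------------

def _annual_dry_means(
    dated_grids: Sequence[tuple[dt.date, RasterGrid]], years: Sequence[int],
) -> np.ndarray:
    """(n_years, rows, cols) mean of valid dry-season observations per year.

    The dry-season window is chosen per pixel row by latitude sign.  Years
    (or pixels) with no valid observation come out NaN.
    """
    if not dated_grids:
        raise RasterError("no observations supplied")
    ref = dated_grids[0][1]
    lat_north = ref.row_lat_centers() >= 0  # per-row hemisphere flag
    out = np.full((len(years), ref.n_rows, ref.n_cols), np.nan)
    for yi, year in enumerate(years):
        for months, row_sel in (((7, 8, 9), lat_north), ((1, 2, 3), ~lat_north)):
            if not row_sel.any():
                continue
            sums = np.zeros(ref.shape)
            counts = np.zeros(ref.shape)
            for date, g in dated_grids:
                if date.year == year and date.month in months:
                    v = g.valid_mask()
                    sums[v] += g.values[v]
                    counts[v] += 1.0
            with np.errstate(invalid="ignore"):
                annual = np.where(counts > 0, sums / np.maximum(counts, 1.0), np.nan)
            out[yi, row_sel, :] = annual[row_sel, :]
    return out


def dry_season_stats(
    index_obs: Sequence[tuple[dt.date, RasterGrid]],
    years: Sequence[int],
    ddof: int = 1,
) -> tuple[RasterGrid, RasterGrid]:
    """Multi-year mean and interannual CV of annual dry-season averages.

    CV is the sample standard deviation (n-1 by default; ``ddof=0`` for
    the population form) of annual values divided by their mean, computed
    over years with data; it needs at least two such years and a mean
    whose magnitude exceeds 1e-6, else nodata.
    """
    ref = index_obs[0][1]
    annual = _annual_dry_means(index_obs, years)
    n_years_valid = np.sum(~np.isnan(annual), axis=0)
    with _quiet_nan():
        mean = np.nanmean(annual, axis=0)
        std = np.full(ref.shape, np.nan)
        enough = n_years_valid >= max(2, ddof + 1)
        std[enough] = np.nanstd(annual, axis=0, ddof=ddof)[enough]
    mean_vals = np.where(n_years_valid > 0, mean, ref.nodata)
    cv_ok = enough & (np.abs(mean) >= CV_MEAN_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv_vals = np.where(cv_ok, std / np.where(cv_ok, mean, 1.0), ref.nodata)
    cv_vals = np.where(cv_ok, np.abs(cv_vals), cv_vals)
    mean_grid = ref.with_values(mean_vals, layer_name="dry_season_mean")
    cv_grid = ref.with_values(np.where(np.isnan(cv_vals), ref.nodata, cv_vals),
                              layer_name="dry_season_cv")
    return mean_grid, cv_grid


# ---------------------------------------------------------------------------
# ETaP — transpiration / precipitation
# ---------------------------------------------------------------------------

def compute_etap(
    transp_monthly: Sequence[tuple[dt.date, RasterGrid]],
    precip_monthly: Sequence[tuple[dt.date, RasterGrid]],
    years: Sequence[int],
) -> RasterGrid:
    """Mean over years of (annual transpiration sum / annual precipitation sum).

    Each year used must have all 12 months in both series, on the same
    calendar.  Years with zero annual precipitation at a pixel are
    excluded from that pixel's mean; pixels with no usable year are nodata.
    """
    t_dates = sorted((d.year, d.month) for d, _ in transp_monthly)
    p_dates = sorted((d.year, d.month) for d, _ in precip_monthly)
    if t_dates != p_dates:
        raise RasterError("mismatched calendars between transpiration and precipitation")
    ref = transp_monthly[0][1]
    t_by = {(d.year, d.month): g for d, g in transp_monthly}
    p_by = {(d.year, d.month): g for d, g in precip_monthly}
    ratios = []
    for year in years:
        months = [(year, m) for m in range(1, 13)]
        if any(k not in t_by for k in months):
            raise RasterError(f"incomplete monthly coverage for year {year}")
        t_sum = np.sum([t_by[k].values for k in months], axis=0)
        p_sum = np.sum([p_by[k].values for k in months], axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratios.append(np.where(p_sum > 0, t_sum / np.where(p_sum > 0, p_sum, 1.0), np.nan))
    stack = np.stack(ratios)
    n_ok = np.sum(~np.isnan(stack), axis=0)
    with _quiet_nan():
        mean = np.nanmean(stack, axis=0)
    return ref.with_values(np.where(n_ok > 0, mean, ref.nodata), layer_name="etap")


# ---------------------------------------------------------------------------
# CTI — compound topographic index
# ---------------------------------------------------------------------------

_D8_OFFSETS = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def _horn_slope_tan(dem: RasterGrid) -> np.ndarray:
    """tan(slope) from Horn's 3x3 operator with metric, latitude-aware spacing."""
    z = dem.values
    # replicate edges so border pixels get one-sided estimates
    zp = np.pad(z, 1, mode="edge")
    dy_m = dem.cell_size * math.pi / 180.0 * 6371007.2
    dx_m = dy_m * np.cos(np.radians(dem.row_lat_centers()))[:, None]
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                  f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1]; i = zp[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx_m)
    dz_dy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * dy_m)
    return np.hypot(dz_dx, dz_dy)


def _d8_accumulation(z: np.ndarray) -> np.ndarray:
    """Upstream cell count per pixel under single-direction steepest descent.

    Flow goes to the neighbour with the largest positive drop per unit
    pixel distance (diagonals sqrt(2)); ties break to the lowest neighbour
    index in the fixed 8-neighbour enumeration; cells with no lower
    neighbour are sinks.
    """
    nr, nc = z.shape
    flat = z.ravel()
    dist = np.array([math.sqrt(di * di + dj * dj) for di, dj in _D8_OFFSETS])
    best = np.full((nr, nc), 0.0)
    tgt = np.full((nr, nc), -1, dtype=np.int64)
    for k, (di, dj) in enumerate(_D8_OFFSETS):
        shifted = np.full((nr, nc), np.inf)
        src = np.s_[max(0, -di) : nr - max(0, di), max(0, -dj) : nc - max(0, dj)]
        dst = np.s_[max(0, di) : nr - max(0, -di), max(0, dj) : nc - max(0, -dj)]
        shifted[src] = z[dst]
        with np.errstate(invalid="ignore"):
            drop = (z - shifted) / dist[k]
        better = drop > best + 1e-15  # strict: earlier (lower) index wins ties
        best = np.where(better, drop, best)
        idx = (np.arange(nr)[:, None] + di) * nc + (np.arange(nc)[None, :] + dj)
        tgt = np.where(better, idx, tgt)
    target = tgt.ravel()
    acc = np.zeros(nr * nc, dtype=np.int64)
    # strictly-descending flow: processing by decreasing elevation is a
    # topological order (ties can't exchange flow)
    order = np.argsort(-flat, kind="stable")
    for cell in order:
        t = target[cell]
        if t >= 0:
            acc[t] += acc[cell] + 1
    return acc.reshape(nr, nc)


def compute_cti(dem: RasterGrid, tan_floor: float = 0.001) -> RasterGrid:
    """CTI = ln((upstream_count + 1) * cell_area_m2 / tan(slope)).

    Slope uses Horn's operator; flow accumulation is D8 steepest descent;
    tan(slope) is floored at ``tan_floor`` so flats stay finite.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise RasterError("CTI needs a DEM of at least 3x3 pixels")
    if not dem.valid_mask().all():
        raise RasterError("CTI requires a gap-free DEM in the analysis window")
    acc = _d8_accumulation(dem.values)
    tanb = np.maximum(_horn_slope_tan(dem), tan_floor)
    area_m2 = dem.cell_areas_km2() * 1e6
    cti = np.log((acc + 1.0) * area_m2 / tanb)
    return dem.with_values(cti, layer_name="cti")


# ---------------------------------------------------------------------------
# LST spatial anomaly
# ---------------------------------------------------------------------------

def _box_mean_valid(values: np.ndarray, valid: np.ndarray, half: int) -> np.ndarray:
    """Mean of valid pixels in a (2*half+1)-sided square window, clipped at
    the grid edge; NaN where the window holds no valid pixel."""
    def window_sum(a: np.ndarray) -> np.ndarray:
        nr, nc = a.shape
        I = np.zeros((nr + 1, nc + 1))
        I[1:, 1:] = np.cumsum(np.cumsum(a, axis=0), axis=1)
        r0 = np.clip(np.arange(nr) - half, 0, None)
        r1 = np.clip(np.arange(nr) + half + 1, None, nr)
        c0 = np.clip(np.arange(nc) - half, 0, None)
        c1 = np.clip(np.arange(nc) + half + 1, None, nc)
        return (I[np.ix_(r1, c1)] - I[np.ix_(r1, c0)]
                - I[np.ix_(r0, c1)] + I[np.ix_(r0, c0)])

    sums = window_sum(np.where(valid, values, 0.0))
    counts = window_sum(valid.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0.5, sums / np.maximum(counts, 1.0), np.nan)


def lst_window_sides_px(pixel_m: float = LST_ASSUMED_PIXEL_M,
                        sides_m: Sequence[float] = LST_WINDOW_SIDES_M) -> tuple[int, ...]:
    """Window sides in (odd) pixels for the anomaly scales.

    The scales are side lengths in metres (270/2700/5400) divided by the
    nominal sensor pixel (30 m by default); even pixel spans round up to
    the next odd count so the window has a center.  At 30 m this gives
    9, 91 and 181.
    """
    out = []
    for side in sides_m:
        n = max(1, int(round(side / pixel_m)))
        out.append(n if n % 2 == 1 else n + 1)
    return tuple(out)


def observation_lst_anomaly(lst: RasterGrid, water: np.ndarray,
                            sides_px: Sequence[int]) -> RasterGrid:
    """Multi-scale anomaly for a single observation.

    anomaly(p) = mean over scales of (lst(p) - window_mean(lst)), with open
    water excluded from every window mean and nodata in the output.
    """
    for side in sides_px:
        if side < 1:
            raise RasterError(f"window side must be >= 1 pixel, got {side}")
    valid = lst.valid_mask() & ~water
    devs = []
    for side in sides_px:
        wmean = _box_mean_valid(lst.values, valid, half=side // 2)
        devs.append(lst.values - wmean)
    with _quiet_nan():
        anom = np.nanmean(np.stack(devs), axis=0)
    out = np.where(valid & ~np.isnan(anom), anom, lst.nodata)
    return lst.with_values(out, layer_name="lst_anom_obs")


def compute_lst_anomaly(
    lst_obs: Sequence[tuple[dt.date, RasterGrid]],
    water_mask: RasterGrid,
    years: Sequence[int],
    sides_px: Sequence[int] | None = None,
) -> RasterGrid:
    """Dry-season multi-year mean of the multi-scale LST spatial anomaly."""
    ref = lst_obs[0][1]
    require_coregistered(ref, water_mask)
    if sides_px is None:
        sides_px = lst_window_sides_px()
    water = water_mask.values == 1.0
    anom_obs = [(date, observation_lst_anomaly(g, water, sides_px))
                for date, g in lst_obs]
    annual = _annual_dry_means(anom_obs, years)
    n_ok = np.sum(~np.isnan(annual), axis=0)
    with _quiet_nan():
        mean = np.nanmean(annual, axis=0)
    out = np.where((n_ok > 0) & ~water, mean, ref.nodata)
    return ref.with_values(out, layer_name="lst_anom")


# ---------------------------------------------------------------------------
# stack assembly
# ---------------------------------------------------------------------------

def assemble_predictors(
    layers: Mapping[str, RasterGrid] | Iterable[tuple[str, RasterGrid]],
) -> PredictorStack:
    """Build the canonical 11-layer stack; refuses omissions and duplicates."""
    if isinstance(layers, Mapping):
        pairs = list(layers.items())
    else:
        pairs = list(layers)
    names = [n for n, _ in pairs]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise RasterError(f"duplicate predictor layer(s): {sorted(dupes)}")
    return PredictorStack(dict(pairs))
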