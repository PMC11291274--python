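"""Downstream analyses over the classified map.

Groundwater storage anomalies are recovered from terrestrial water
storage by removing soil moisture, snow water equivalent and canopy
water (GWS = TWS - SM - SWE - canopy, in cm equivalent water thickness);
their linear trends are ordinary least squares over a fixed date window
(default April 2002-April 2022).  The remaining operations are
area-weighted summaries over the GDE area-density layer: the fraction of
GDE area over declining groundwater storage, zonal means over polygon
regions (e.g. freshwater ecoregions), protection-status fractions
against protected-area and policy-jurisdiction layers, and the share of
GDE area on cells where a covariate (e.g. pastoral land-use density)
exceeds a cutoff.

"Declining" means a negative trend slope — sign only, no significance
filter; the slope standard error is reported alongside for users who
want one.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry.base import BaseGeometry

from .raster_core import RasterGrid, RasterError, require_coregistered
from .synthetic_scene import StorageSeries

TREND_WINDOW_DEFAULT = (dt.date(2002, 4, 1), dt.date(2022, 4, 30))
MIN_TREND_MONTHS = 24


class PosthocError(ValueError):
    """Contract violation in a post hoc analysis input."""


@dataclass
class TrendGrid:
    """Per-cell storage trend (cm/yr) with its validity mask and window."""

    slope: RasterGrid
    window: tuple[dt.date, dt.date]
    valid_mask: RasterGrid


@dataclass
class ProtectionLayers:
    """Binary protected-area and policy-jurisdiction rasters."""

    protected_area: RasterGrid
    policy_jurisdiction: RasterGrid


# ---------------------------------------------------------------------------
# storage decomposition and trends
# ---------------------------------------------------------------------------

def gws_anomaly(series: StorageSeries) -> np.ndarray:
    """Groundwater storage anomaly: tws - sm - swe - canopy, elementwise."""
    n = len(series.dates)
    for name in ("tws", "sm", "swe", "canopy"):
        comp = getattr(series, name)
        if len(comp) != n:
            raise PosthocError(
                f"misaligned dates: component {name!r} has {len(comp)} "
                f"values for {n} dates"
            )
    return series.tws - series.sm - series.swe - series.canopy


def _decimal_years(dates: pd.DatetimeIndex) -> np.ndarray:
    # month-resolution decimal time: exactly uniform for monthly series, so
    # a seasonal sinusoid over whole years is orthogonal to the trend term
    d = pd.DatetimeIndex(dates)
    return np.asarray(d.year, float) + (np.asarray(d.month, float) - 1) / 12.0


def ols_trend(
    dates: pd.DatetimeIndex,
    values: np.ndarray,
    window: tuple[dt.date, dt.date] = TREND_WINDOW_DEFAULT,
    seasonal: bool = True,
) -> tuple[float, float]:
    """Least-squares trend slope (per year) and its standard error.

    The fit regresses the anomaly on decimal time together with annual
    and semiannual harmonics (the standard treatment for monthly storage
    series; ``seasonal=False`` drops the harmonics).  Co-estimating the
    harmonics keeps the slope free of seasonal leakage: with discrete
    monthly sampling a raw slope-on-time fit picks up a small alias of
    any seasonal cycle that does not span whole years.  Months missing
    from the series are simply absent from the fit; fewer than 24
    in-window months is an error.
    """
    d = pd.DatetimeIndex(dates)
    v = np.asarray(values, float)
    start, end = (pd.Timestamp(w) for w in window)
    sel = (d >= start) & (d <= end) & ~np.isnan(v)
    if sel.sum() < MIN_TREND_MONTHS:
        raise PosthocError(
            f"trend needs >= {MIN_TREND_MONTHS} in-window months, got {int(sel.sum())}"
        )
    t = _decimal_years(d[sel])
    y = v[sel]
    tc = t - t.mean()
    cols = [np.ones(len(t)), tc]
    if seasonal:
        w_ann = 2.0 * np.pi * t
        cols += [np.sin(w_ann), np.cos(w_ann), np.sin(2 * w_ann), np.cos(2 * w_ann)]
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope = float(coef[1])
    dof = len(t) - X.shape[1]
    resid = y - X @ coef
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        se = float(np.sqrt(cov[1, 1]))
    else:
        se = float("nan")
    return slope, se


def gws_trend(series: StorageSeries,
              window: tuple[dt.date, dt.date] = TREND_WINDOW_DEFAULT) -> tuple[float, float]:
    """Trend of the decomposed groundwater anomaly series."""
    return ols_trend(series.dates, gws_anomaly(series), window)


# ---------------------------------------------------------------------------
# density x trend analyses
# ---------------------------------------------------------------------------

def fraction_declining(gde_density: RasterGrid, trend: TrendGrid) -> float:
    """Share of GDE area lying over declining (negative-trend) groundwater.

    Area-weighted: sum of density x cell area over valid cells with
    negative slope, divided by the same sum over all valid cells.  Cells
    outside the trend validity mask drop from numerator and denominator
    alike ("among areas with available data").
    """
    require_coregistered(gde_density, trend.slope, trend.valid_mask)
    dens_ok = gde_density.valid_mask()
    slope_ok = trend.slope.valid_mask() & (trend.valid_mask.values == 1.0)
    use = dens_ok & slope_ok
    areas = gde_density.cell_areas_km2()
    weights = gde_density.values * areas
    denom = float(np.sum(weights[use]))
    if denom <= 0:
        raise PosthocError("no GDE area over cells with trend data")
    numer = float(np.sum(weights[use & (trend.slope.values < 0)]))
    return numer / denom


def threshold_overlap(gde_density: RasterGrid, covariate_density: RasterGrid,
                      cutoff: float) -> float:
    """Share of GDE area on cells where the covariate strictly exceeds ``cutoff``.

    Cells with covariate nodata drop from numerator and denominator.
    """
    require_coregistered(gde_density, covariate_density)
    use = gde_density.valid_mask() & covariate_density.valid_mask()
    weights = gde_density.values * gde_density.cell_areas_km2()
    denom = float(np.sum(weights[use]))
    if denom <= 0:
        raise PosthocError("no GDE area over cells with covariate data")
    numer = float(np.sum(weights[use & (covariate_density.values > cutoff)]))
    return numer / denom


# ---------------------------------------------------------------------------
# zonal and protection summaries
# ---------------------------------------------------------------------------

def zonal_area_weighted_mean(
    value: RasterGrid, zones: list[tuple[str, BaseGeometry]],
) -> pd.DataFrame:
    """Area-weighted mean of ``value`` per zone polygon.

    A cell belongs to a zone when its center falls inside the polygon
    (even-odd rule of the geometry library).  Zones covering no valid
    cell report NaN.
    """
    valid = value.valid_mask()
    areas = value.cell_areas_km2()
    lons = np.broadcast_to(value.col_lon_centers()[None, :], value.shape)
    lats = np.broadcast_to(value.row_lat_centers()[:, None], value.shape)
    records = []
    for name, geom in zones:
        if not geom.is_valid:
            raise PosthocError(f"invalid polygon for zone {name!r}")
        inside = contains_xy(geom, lons.ravel(), lats.ravel()).reshape(value.shape)
        use = inside & valid
        if use.any():
            mean = float(np.sum(value.values[use] * areas[use]) / np.sum(areas[use]))
        else:
            mean = float("nan")
        records.append({"zone": name, "mean": mean, "n_cells": int(use.sum())})
    return pd.DataFrame.from_records(records)


def protection_fraction(gde_binary: RasterGrid,
                        layers: ProtectionLayers) -> dict[str, float]:
    """Area fractions of mapped GDE pixels by protection category.

    Categories (unprotected / protected_area_only / policy_only / both)
    partition GDE area exactly; ``any`` is their complement of
    unprotected.
    """
    require_coregistered(gde_binary, layers.protected_area, layers.policy_jurisdiction)
    gde = gde_binary.valid_mask() & (gde_binary.values == 1.0)
    if not gde.any():
        raise PosthocError("no GDE pixels in the classification map")
    areas = gde_binary.cell_areas_km2()
    pa = layers.protected_area.values == 1.0
    pol = layers.policy_jurisdiction.values == 1.0
    total = float(np.sum(areas[gde]))
    cats = {
        "unprotected": gde & ~pa & ~pol,
        "protected_area_only": gde & pa & ~pol,
        "policy_only": gde & ~pa & pol,
        "both": gde & pa & pol,
    }
    out = {k: float(np.sum(areas[m])) / total for k, m in cats.items()}
    out["any"] = 1.0 - out["unprotected"]
    return out
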