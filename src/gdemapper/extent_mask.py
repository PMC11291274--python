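"""Model-extent construction: dryland climate, land-cover and depth-to-groundwater masks.

The analysis extent is the pixelwise conjunction of three binary masks:

* climate: arid/semi-arid (Koeppen type B) and dry-summer temperate (Csa,
  Csb, Csc) classes are in; humid and cold classes are out;
* land cover: agricultural, urban and open-water pixels are out;
* depth to groundwater (DTG): pixels deeper than 30 m are out, beyond the
  rooting zone of most phreatophytic vegetation.

The DTG layer is gap-filled before thresholding: open-water pixels get
DTG 0, isolated nodata pixels get the 1.5-pixel focal mean of their valid
neighbours, and any pixel still missing after that is assumed shallow and
set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import (
    RasterGrid,
    RasterError,
    focal_mean,
    require_coregistered,
)

# Climate vocabulary: integer codes on the grid <-> class names.  Mapping
# real Koeppen-Geiger codes onto this vocabulary is the caller's job.
CLIMATE_CODES: dict[str, int] = {
    "B": 1, "Csa": 2, "Csb": 3, "Csc": 4, "humid": 5, "cold": 6,
}
DRYLAND_CLASSES = frozenset({"B", "Csa", "Csb", "Csc"})

# Land-cover vocabulary (one collapsed layer stands in for the separate
# agriculture/urban and ocean products used at global scale).
LANDCOVER_CODES: dict[str, int] = {
    "shrubland": 1, "grassland": 2, "barren": 3,
    "cropland": 4, "built": 5, "water": 6,
}
MASKED_LANDCOVER = frozenset({"cropland", "built", "water"})

DTG_MAX_DEFAULT = 30.0  # metres; inclusive cutoff


@dataclass
class ExtentMasks:
    """The three component masks, their conjunction, and the analysed area."""

    climate_ok: RasterGrid
    landcover_ok: RasterGrid
    dtg_ok: RasterGrid
    extent: RasterGrid
    analysed_area_km2: float


def _code_mask(grid: RasterGrid, vocabulary: dict[str, int], ok_names: frozenset[str],
               layer_name: str) -> RasterGrid:
    valid = grid.valid_mask()
    codes = grid.values
    known = np.isin(codes, list(vocabulary.values()))
    unknown = valid & ~known
    if unknown.any():
        raise RasterError(
            f"unknown class code {codes[unknown][0]!r} in layer "
            f"{grid.layer_name or layer_name!r}"
        )
    ok_codes = [vocabulary[name] for name in ok_names]
    out = np.where(valid, np.isin(codes, ok_codes).astype(float), grid.nodata)
    return grid.with_values(out, layer_name=layer_name)


def climate_mask(climate_class: RasterGrid,
                 allowed: frozenset[str] | set[str] = DRYLAND_CLASSES) -> RasterGrid:
    """1 where the climate class is in ``allowed``, 0 elsewhere; nodata propagates."""
    unknown_names = set(allowed) - set(CLIMATE_CODES)
    if unknown_names:
        raise RasterError(f"unknown climate class name(s): {sorted(unknown_names)}")
    return _code_mask(climate_class, CLIMATE_CODES, frozenset(allowed), "climate_ok")


def landcover_mask(landcover: RasterGrid) -> RasterGrid:
    """0 for cropland, built-up and open water; 1 for all other cover; nodata propagates."""
    keep = frozenset(LANDCOVER_CODES) - MASKED_LANDCOVER
    return _code_mask(landcover, LANDCOVER_CODES, keep, "landcover_ok")


def water_mask(landcover: RasterGrid) -> RasterGrid:
    """1 on open-water pixels, 0 elsewhere (used by DTG filling and LST anomalies)."""
    return _code_mask(landcover, LANDCOVER_CODES, frozenset({"water"}), "water")


def fill_dtg(dtg: RasterGrid, open_water: RasterGrid,
             water_adjacent_only: bool = False) -> RasterGrid:
    """Gap-fill depth-to-groundwater.

    Step 1: open-water pixels get DTG 0 (the source data has gaps there).
    Step 2: remaining isolated nodata pixels get the 1.5-pixel focal mean
    of valid neighbours.  Step 3: anything still missing is assumed
    shallow and set to 0 — unconditionally by default, or only when
    8-adjacent to open water if ``water_adjacent_only`` is set (a stricter
    reading; non-adjacent gaps then stay nodata).  Valid input values are
    never altered, so the operation is idempotent.
    """
    require_coregistered(dtg, open_water)
    vals = dtg.values.copy()
    water = open_water.values == 1.0
    vals[water] = 0.0
    step1 = dtg.with_values(vals)
    step2 = focal_mean(step1, radius_px=1.5, fill_only=True)
    out = step2.values.copy()
    still_missing = ~step2.valid_mask()
    if water_adjacent_only:
        from scipy import ndimage
        near_water = ndimage.binary_dilation(water, structure=np.ones((3, 3), bool))
        out[still_missing & near_water] = 0.0
    else:
        out[still_missing] = 0.0
    return dtg.with_values(out, layer_name="dtg_filled")


def build_extent(climate_ok: RasterGrid, landcover_ok: RasterGrid,
                 dtg_filled: RasterGrid, dtg_max: float = DTG_MAX_DEFAULT) -> ExtentMasks:
    """Conjoin the component masks; DTG cutoff is inclusive (<= ``dtg_max``)."""
    require_coregistered(climate_ok, landcover_ok, dtg_filled)
    dtg_valid = dtg_filled.valid_mask()
    dtg_ok_vals = np.where(
        dtg_valid, (dtg_filled.values <= dtg_max).astype(float), dtg_filled.nodata
    )
    dtg_ok = dtg_filled.with_values(dtg_ok_vals, layer_name="dtg_ok")

    masks = [climate_ok, landcover_ok, dtg_ok]
    all_valid = np.logical_and.reduce([m.valid_mask() for m in masks])
    conj = np.logical_and.reduce([m.values == 1.0 for m in masks])
    extent_vals = np.where(all_valid, conj.astype(float), climate_ok.nodata)
    extent = climate_ok.with_values(extent_vals, layer_name="extent")

    areas = extent.cell_areas_km2()
    analysed = float(np.sum(areas[all_valid & conj]))
    return ExtentMasks(
        climate_ok=climate_ok,
        landcover_ok=landcover_ok,
        dtg_ok=dtg_ok,
        extent=extent,
        analysed_area_km2=analysed,
    )
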