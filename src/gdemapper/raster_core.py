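"""Grid data model, focal statistics, block aggregation, geodesic areas and I/O.

Every gridded quantity in the pipeline (depth to groundwater, spectral
indices, land-surface-temperature anomalies, classification maps, area
densities) travels as a :class:`RasterGrid`: a north-up, geographic
(lon/lat, WGS84) rectangular array with a nodata sentinel.  Pixel
coordinates are row-major and 0-based and refer to pixel centers; the
georeference is the north-west corner of the grid plus a square cell size
in degrees.  Projected coordinate systems are out of scope.

Rasters are stored on disk as single-band ESRI ASCII grids (plain text,
``.asc``), points as CSV with columns ``lon,lat,label,source,region`` and
polygons as GeoJSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

#: Authalic (equal-area sphere) Earth radius in km.
EARTH_RADIUS_KM = 6371.0072

#: Default nodata sentinel; compared by exact equality.
DEFAULT_NODATA = -9999.0

VALID_LABELS = frozenset({"GDE", "NONGDE"})


class RasterError(ValueError):
    """Invalid raster input or parameter."""


class ParseError(ValueError):
    """Malformed file content; the message names the offending field."""


@dataclass
class RasterGrid:
    """A rectangular georeferenced grid of real values.

    Parameters
    ----------
    values
        2-D float array; ``nodata`` marks missing cells.
    origin_lon, origin_lat
        Longitude of the west edge and latitude of the north edge of the
        grid (the north-west corner), in degrees.
    cell_size
        Pixel size in degrees (square pixels); row index increases
        southward.
    nodata
        Sentinel for missing values, matched by exact equality.
    layer_name
        Free-text name of the quantity held by the grid.
    """

    values: np.ndarray
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    cell_size: float = 1.0 / 3600.0  # 1 arcsecond, ~30 m at the equator
    nodata: float = DEFAULT_NODATA
    layer_name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterError("RasterGrid values must be 2-D")
        if self.cell_size <= 0:
            raise RasterError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells holding data (not nodata, not NaN)."""
        return (self.values != self.nodata) & ~np.isnan(self.values)

    def row_lat_centers(self) -> np.ndarray:
        """Latitude of each row's pixel centers (degrees), north to south."""
        rows = np.arange(self.n_rows)
        return self.origin_lat - (rows + 0.5) * self.cell_size

    def col_lon_centers(self) -> np.ndarray:
        """Longitude of each column's pixel centers (degrees)."""
        cols = np.arange(self.n_cols)
        return self.origin_lon + (cols + 0.5) * self.cell_size

    def cell_areas_km2(self) -> np.ndarray:
        """Geodesic area of every cell, shape (n_rows, n_cols), km^2."""
        per_row = np.array(
            [cell_area_km2(lat, self.cell_size) for lat in self.row_lat_centers()]
        )
        return np.repeat(per_row[:, None], self.n_cols, axis=1)

    def lonlat_to_rowcol(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to the row/col of the containing pixel."""
        col = np.floor((np.asarray(lon) - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - np.asarray(lat)) / self.cell_size).astype(int)
        return row, col

    def same_georef(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.origin_lon, other.origin_lon, abs_tol=1e-12)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=1e-12)
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-12)
        )

    def with_values(self, values: np.ndarray, layer_name: str | None = None) -> "RasterGrid":
        """A copy of this grid's georeference carrying new values."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            layer_name=self.layer_name if layer_name is None else layer_name,
        )


def require_coregistered(*grids: RasterGrid) -> None:
    """Raise :class:`RasterError` unless all grids share shape and georeference."""
    first = grids[0]
    for g in grids[1:]:
        if not first.same_georef(g):
            raise RasterError(
                f"grids not co-registered: {first.layer_name or 'grid'} "
                f"{first.shape} vs {g.layer_name or 'grid'} {g.shape}"
            )


# ---------------------------------------------------------------------------
# geodesic areas
# ---------------------------------------------------------------------------

def cell_area_km2(lat_center: float, cell_size: float) -> float:
    """Area of a lon/lat cell as a spherical quadrangle, in km^2.

    Uses the authalic sphere: ``A = R^2 * dlam * (sin(phi_top) - sin(phi_bot))``
    with edge latitudes clamped to +-90 degrees, so polar cells get their
    true (reduced) area.
    """
    if abs(lat_center) > 90:
        raise RasterError(f"|lat_center| must be <= 90, got {lat_center}")
    phi_top = math.radians(min(lat_center + cell_size / 2.0, 90.0))
    phi_bot = math.radians(max(lat_center - cell_size / 2.0, -90.0))
    dlam = math.radians(cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (math.sin(phi_top) - math.sin(phi_bot))


# ---------------------------------------------------------------------------
# focal statistics
# ---------------------------------------------------------------------------

def circular_footprint(radius_px: float) -> np.ndarray:
    """Boolean kernel of pixel-center offsets within ``radius_px`` (Euclidean)."""
    r = int(math.floor(radius_px))
    di, dj = np.mgrid[-r : r + 1, -r : r + 1]
    return (di**2 + dj**2) <= radius_px**2 + 1e-12


def focal_mean(grid: RasterGrid, radius_px: float, fill_only: bool = False) -> RasterGrid:
    """Mean of valid neighbours whose centers lie within ``radius_px`` pixels.

    The focal pixel is included.  With ``fill_only`` set, valid pixels pass
    through unchanged and only nodata pixels receive the neighbourhood
    mean; pixels with no valid neighbour stay nodata.  A radius of 1.5
    yields the 8-connected 3x3 neighbourhood plus center.
    """
    if radius_px < 1:
        raise RasterError(f"radius_px must be >= 1, got {radius_px}")
    footprint = circular_footprint(radius_px).astype(float)
    valid = grid.valid_mask()
    filled = np.where(valid, grid.values, 0.0)
    # zero-padding outside the grid: border windows shrink to in-grid cells
    sums = ndimage.correlate(filled, footprint, mode="constant", cval=0.0)
    counts = ndimage.correlate(valid.astype(float), footprint, mode="constant", cval=0.0)
    counts_int = np.rint(counts)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts_int > 0, sums / np.maximum(counts, 1e-300), grid.nodata)
    if fill_only:
        out = np.where(valid, grid.values, mean)
    else:
        out = mean
    return grid.with_values(out)


# ---------------------------------------------------------------------------
# block aggregation
# ---------------------------------------------------------------------------

def aggregate_fraction(
    binary: RasterGrid, block: int, valid_denominator: bool = False
) -> RasterGrid:
    """Area fraction of 1-pixels per ``block`` x ``block`` cell.

    The numerator is the geodesic area of 1-pixels in the block; the
    denominator is the total block area (nodata pixels included) unless
    ``valid_denominator`` is set, in which case only valid-pixel area
    counts.  Trailing partial blocks are computed over their actual
    extent, so block area sums conserve exactly.  Blocks that are
    entirely nodata come out nodata.
    """
    if block < 1:
        raise RasterError(f"block must be a positive integer, got {block}")
    valid = binary.valid_mask()
    vals = binary.values
    bad = valid & ~np.isin(vals, (0.0, 1.0))
    if bad.any():
        raise RasterError(
            f"aggregate_fraction input must be binary; found value {vals[bad][0]!r}"
        )
    areas = binary.cell_areas_km2()
    nr = math.ceil(binary.n_rows / block)
    nc = math.ceil(binary.n_cols / block)
    out = np.full((nr, nc), binary.nodata)
    for bi in range(nr):
        for bj in range(nc):
            sl = np.s_[bi * block : (bi + 1) * block, bj * block : (bj + 1) * block]
            v, a, m = vals[sl], areas[sl], valid[sl]
            if not m.any():
                continue
            numer = float(np.sum(a[m & (v == 1.0)]))
            denom = float(np.sum(a[m])) if valid_denominator else float(np.sum(a))
            out[bi, bj] = numer / denom
    name = binary.layer_name + ("_fraction_valid" if valid_denominator else "_fraction")
    return RasterGrid(
        out,
        origin_lon=binary.origin_lon,
        origin_lat=binary.origin_lat,
        cell_size=binary.cell_size * block,
        nodata=binary.nodata,
        layer_name=name,
    )


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid, CSV points, GeoJSON polygons
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> None:
    """Write as a single-band ESRI ASCII grid (lossless, %.17g values)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_lon!r}\n")
        fh.write(f"yllcorner {grid.origin_lat - grid.n_rows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_raster(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid; layer name taken from the file stem."""
    path = Path(path)
    header: dict[str, float] = {}
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                try:
                    header[key] = float(parts[1])
                except (IndexError, ValueError) as exc:
                    raise ParseError(f"bad header field {parts[0]!r} in {path}") from exc
            else:
                try:
                    rows.append(np.array([float(v) for v in parts]))
                except ValueError as exc:
                    raise ParseError(f"non-numeric raster value in {path}") from exc
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ParseError(f"missing header field {req!r} in {path}")
    values = np.vstack(rows) if rows else np.empty((0, 0))
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ParseError(
            f"field nrows/ncols mismatch in {path}: header says "
            f"{int(header['nrows'])}x{int(header['ncols'])}, data is {values.shape}"
        )
    cell = header["cellsize"]
    return RasterGrid(
        values,
        origin_lon=header["xllcorner"],
        origin_lat=header["yllcorner"] + values.shape[0] * cell,
        cell_size=cell,
        nodata=header.get("nodata_value", DEFAULT_NODATA),
        layer_name=path.stem,
    )


def read_points(path: str | Path) -> pd.DataFrame:
    """Read a point table (CSV: lon,lat[,label][,source][,region]).

    Labels, when present, must be GDE or NONGDE.
    """
    df = pd.read_csv(path)
    for req in ("lon", "lat"):
        if req not in df.columns:
            raise ParseError(f"point table missing field {req!r}: {path}")
    if "label" in df.columns:
        labels = df["label"].dropna()
        bad = labels[~labels.isin(VALID_LABELS)]
        if len(bad):
            raise ParseError(
                f"field 'label' has invalid value {bad.iloc[0]!r} in {path} "
                f"(allowed: {sorted(VALID_LABELS)})"
            )
    for opt in ("source", "region"):
        if opt not in df.columns:
            df[opt] = ""
    return df


def write_points(points: pd.DataFrame, path: str | Path) -> None:
    points.to_csv(path, index=False)


def _check_rings_closed(geometry: dict, path: str | Path) -> None:
    gtype = geometry.get("type")
    if gtype == "Polygon":
        ring_sets = [geometry["coordinates"]]
    elif gtype == "MultiPolygon":
        ring_sets = geometry["coordinates"]
    else:
        return
    for rings in ring_sets:
        for ring in rings:
            if len(ring) < 4 or list(ring[0]) != list(ring[-1]):
                raise ParseError(
                    f"field 'coordinates': polygon ring not closed in {path}"
                )


def read_polygons(path: str | Path) -> list[tuple[str, BaseGeometry]]:
    """Read (name, geometry) pairs from a GeoJSON FeatureCollection (WGS84)."""
    path = Path(path)
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON in {path}: {exc}") from exc
    if doc.get("type") == "FeatureCollection":
        features = doc.get("features", [])
    elif doc.get("type") == "Feature":
        features = [doc]
    else:
        raise ParseError(f"field 'type' must be FeatureCollection or Feature in {path}")
    out = []
    for i, feat in enumerate(features):
        geom_dict = feat.get("geometry")
        if geom_dict is None:
            raise ParseError(f"field 'geometry' missing on feature {i} in {path}")
        _check_rings_closed(geom_dict, path)
        geom = _shapely_shape(geom_dict)
        props = feat.get("properties") or {}
        name = str(props.get("name", f"zone_{i}"))
        out.append((name, geom))
    return out
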