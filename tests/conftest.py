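import numpy as np
import pytest

from gdemapper import pipeline as pl
from gdemapper import synthetic_scene as ss
from gdemapper.raster_core import RasterGrid


@pytest.fixture(scope="session")
def small_bundle() -> ss.SceneBundle:
    """An 80x80, 3-year scene with default contrast, shared across tests."""
    cfg = ss.ScenarioConfig(n_rows=80, n_cols=80, n_years=3, seed=11)
    return ss.generate_scene(cfg)


@pytest.fixture(scope="session")
def small_stack(small_bundle):
    return pl.compute_predictor_stack(small_bundle)


@pytest.fixture(scope="session")
def small_points(small_bundle):
    return ss.sample_points(small_bundle, 300, 300, 60, seed=12)


def make_grid(values, lat0=0.001, lon0=0.0, cell=1.0 / 3600.0, nodata=-9999.0,
              name="test") -> RasterGrid:
    """Near-equator test grid (cell areas equal to ~1e-8 relative)."""
    return RasterGrid(np.asarray(values, float), origin_lon=lon0, origin_lat=lat0,
                      cell_size=cell, nodata=nodata, layer_name=name)
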