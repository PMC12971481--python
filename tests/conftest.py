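import numpy as np
import pytest

from avitwin.core import CellIndex, GridSpec, RasterLayer


@pytest.fixture
def coarse_grid() -> GridSpec:
    """An 8x8 grid of 1 km cells."""
    return GridSpec(origin_easting_km=0.0, origin_northing_km=8.0, cell_size_km=1.0, n_rows=8, n_cols=8)


@pytest.fixture
def fine_grid() -> GridSpec:
    """A 40x40 grid of 1-ha cells nesting 10x10 into a 4x4 km grid."""
    return GridSpec(origin_easting_km=0.0, origin_northing_km=4.0, cell_size_km=0.1, n_rows=40, n_cols=40)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240401)


@pytest.fixture
def random_spatial_instance(coarse_grid, rng):
    """Records scattered over the 8x8 grid with known m*d products and detections."""
    n = 2500
    rows = rng.integers(0, 8, n)
    cols = rng.integers(0, 8, n)
    a = rng.uniform(0.01, 0.6, n)
    y = (rng.random(n) < a * 0.5).astype(float)
    prior_mean = RasterLayer(coarse_grid, rng.uniform(0.15, 0.85, (8, 8)))
    prior_sd = RasterLayer(coarse_grid, np.full((8, 8), 0.15))
    return y, a, rows, cols, prior_mean, prior_sd
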