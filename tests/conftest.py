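import numpy as np
import pytest

from landrisk import LandUseRaster, build_grid


@pytest.fixture
def toy_raster() -> LandUseRaster:
    """Canonical two-class worked example: 4x4 grid at 500 m pixels
    (A = 4 km²); water (code 5) the 2x2 top-left block, grass (code 3)
    the remaining 12 pixels."""
    codes = np.full((4, 4), 3)
    codes[:2, :2] = 5
    return LandUseRaster(codes, 500.0)


@pytest.fixture
def toy_grid(toy_raster):
    """Single risk cell covering the whole toy landscape."""
    return build_grid(toy_raster, 2000.0)


def random_landuse(rng: np.random.Generator, shape=(64, 64), pixel_size=100.0,
                   codes=(1, 2, 3, 4, 5), nodata_frac=0.0) -> LandUseRaster:
    grid = rng.choice(codes, size=shape)
    if nodata_frac > 0:
        mask = rng.random(shape) < nodata_frac
        grid = np.where(mask, -9999, grid)
    return LandUseRaster(grid.astype(np.int64), pixel_size)
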