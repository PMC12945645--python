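import numpy as np
import pytest

from mmnds.volumes import GridSpec, ScalarVolume, BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """8^3 grid at 2 mm, origin at world (0,0,0)."""
    return GridSpec(shape=(8, 8, 8), voxel_size_mm=(2.0, 2.0, 2.0))


@pytest.fixture
def unit_grid():
    """16^3 grid at 1 mm centered near the origin."""
    return GridSpec(shape=(16, 16, 16), voxel_size_mm=(1.0, 1.0, 1.0),
                    origin_mm=(-7.5, -7.5, -7.5))


@pytest.fixture
def random_volume(small_grid, rng):
    return ScalarVolume(small_grid, rng.normal(1.0, 0.3, small_grid.shape))


@pytest.fixture
def full_mask(small_grid):
    return BinaryMask(small_grid, np.ones(small_grid.shape, dtype=bool))
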