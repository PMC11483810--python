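import warnings

import numpy as np
import pytest

from mesoreg import phantom as ph
from mesoreg.core import BinaryMask, Grid3D, Volume

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def desk_grid():
    return ph.desk_grid()


@pytest.fixture(scope="session")
def small_iso_grid():
    """Tiny isotropic grid for fast geometric tests."""
    return Grid3D((24, 24, 24), (20.0, 20.0, 20.0))


@pytest.fixture(scope="session")
def desk_tree(desk_grid):
    return ph.generate_vessel_tree(desk_grid, seed=7)


@pytest.fixture(scope="session")
def rigid_pair(desk_grid, desk_tree):
    """One desk-scale rigid phantom pair with default variability."""
    return ph.make_pair(desk_tree, desk_grid, {"kind": "rigid"}, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(10, 10, 10), p=0.2, spacing=(20.0, 20.0, 20.0)) -> BinaryMask:
    grid = Grid3D(shape, spacing)
    vals = (rng.uniform(size=shape) < p).astype(np.uint8)
    return BinaryMask(grid, vals)


def random_volume(rng, shape=(10, 10, 10), spacing=(20.0, 20.0, 20.0)) -> Volume:
    grid = Grid3D(shape, spacing)
    return Volume(grid, rng.normal(size=shape).astype(np.float32))
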