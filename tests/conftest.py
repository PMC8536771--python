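import numpy as np
import pytest

from greenblue import synth
from greenblue.raster import RasterGrid


@pytest.fixture(scope="session")
def mini_landscape():
    """Small one-valley fixture shared by fast tests."""
    return synth.generate(synth.preset("mini", seed=1))


@pytest.fixture(scope="session")
def standard_landscape():
    """The 200x200 two-valleys-six-patches fixture."""
    return synth.generate(synth.preset("two-valleys-six-patches", seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dem(rng, nrows, ncols, cell_size=1.0):
    return RasterGrid(rng.uniform(0.0, 50.0, size=(nrows, ncols)), cell_size)


def random_surface(rng, nrows, ncols, cell_size=1.0):
    return RasterGrid(rng.uniform(0.5, 20.0, size=(nrows, ncols)), cell_size)
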