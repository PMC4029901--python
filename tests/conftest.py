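import numpy as np
import pytest

from isoassign.grids import RasterGrid
from isoassign.simulate import SimulationConfig, make_stack, simulate_feathers


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_grid():
    """5x5 grid with one invalid cell, 1-degree cells anchored at the origin."""
    vals = np.arange(25, dtype=float).reshape(5, 5)
    vals[1, 3] = np.nan
    return RasterGrid(values=vals, xllcorner=0.0, yllcorner=0.0, cellsize=1.0)


@pytest.fixture(scope="session")
def default_cfg():
    return SimulationConfig(seed=17)


@pytest.fixture(scope="session")
def stack(default_cfg):
    return make_stack(default_cfg)


@pytest.fixture(scope="session")
def cohort(default_cfg, stack):
    """Default synthetic cohort (36/24/15) with its truth table."""
    return simulate_feathers(default_cfg, stack)


def random_grid(rng, shape=(6, 7), frac_invalid=0.15, lo=-120.0, hi=40.0):
    vals = rng.uniform(lo, hi, size=shape)
    mask = rng.random(shape) < frac_invalid
    vals[mask] = np.nan
    if np.all(np.isnan(vals)):
        vals[0, 0] = lo
    return RasterGrid(values=vals, xllcorner=-10.0, yllcorner=-20.0, cellsize=0.33)
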