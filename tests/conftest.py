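import numpy as np
import pytest

from hopperband.grids import FoodField, PopulationField, SpatialGrid, StateDim, StateGrid
from hopperband.model import ModelParams


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def validation_params():
    """Configuration of the steady-state validation study (weak, long-range attraction)."""
    return ModelParams(D=0.01, gamma=60.0, A=1.0, r=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    return SpatialGrid(L=3.0, nx=64)


@pytest.fixture
def active_states():
    return StateGrid(StateDim("ng", 6), StateDim("nh", 5))


@pytest.fixture
def random_fields(rng, small_grid, active_states):
    """A strictly positive random population plus food, for invariance checks."""
    vals = rng.random((small_grid.nx,) + active_states.shape) * 4.0 + 0.1
    rho = PopulationField(small_grid, active_states, vals)
    food = FoodField(small_grid, rng.random(small_grid.nx) * 2.0)
    return rho, food


def frozen_field(grid, ng, nh, rho_bar):
    """Population at a single frozen point state with a given spatial marginal."""
    sg = StateGrid(StateDim.fixed("ng", ng), StateDim.fixed("nh", nh))
    return PopulationField(grid, sg, np.asarray(rho_bar, dtype=float)[:, None, None])
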