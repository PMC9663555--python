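import numpy as np
import pytest

from resburn.attribution import attribute
from resburn.diurnal import apply_kernel, build_triangular_kernel
from resburn.synthetic_world import (
    GridSpec,
    PopulationGrid,
    TransportConfig,
    WorldConfig,
    build_adjoint,
    make_emissions,
    make_world,
)


@pytest.fixture(scope="session")
def default_world():
    """The 6x6-cell, 60-day hourly world, seed 1."""
    return make_world(WorldConfig(seed=1))


@pytest.fixture(scope="session")
def default_emissions(default_world):
    w = default_world
    return make_emissions(
        w.crops, w.regions, w.grid, seed=1, season_of_day=w.season_of_day
    )


@pytest.fixture(scope="session")
def default_kernel():
    return build_triangular_kernel()


@pytest.fixture(scope="session")
def default_hourly(default_emissions, default_kernel):
    return apply_kernel(default_emissions, default_kernel)


@pytest.fixture(scope="session")
def default_sensitivity(default_world):
    w = default_world
    return build_adjoint(w.transport, w.grid, w.pop)


@pytest.fixture(scope="session")
def default_contribution(default_sensitivity, default_hourly):
    return attribute(default_sensitivity, default_hourly)


@pytest.fixture(scope="session")
def small_grid():
    """4x4 grid, 2 days hourly = 48 steps, for dense-matrix oracles."""
    return GridSpec(n_lon=4, n_lat=4, cell_area=500.0, n_days=2, steps_per_day=24)


@pytest.fixture(scope="session")
def small_transport():
    return TransportConfig(
        wind=(0.4, 0.2), diffusion=0.05, deposition_rate=0.08, emission_scale=3.0
    )


@pytest.fixture(scope="session")
def small_pop(small_grid):
    rng = np.random.default_rng(7)
    rho = rng.uniform(10.0, 5000.0, size=small_grid.shape)
    return PopulationGrid(rho=rho)
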