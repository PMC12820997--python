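import numpy as np
import pytest

from piezospt.simulate import (
    SimulationConfig,
    simulate_brownian,
    simulate_immobile,
    simulate_two_state,
)
from piezospt.trajectory import Trajectory


@pytest.fixture(scope="session")
def immobile_ensemble():
    """1000 noise-only trajectories, 200 points, sigma = 0.02 um."""
    cfg = SimulationConfig(n_traj=1000, n_points=200, dt=0.1, loc_sigma=0.02, seed=101)
    return simulate_immobile(cfg)


@pytest.fixture(scope="session")
def brownian_ensemble():
    """500 noise-free Brownian trajectories, D = 0.1 um^2/s."""
    cfg = SimulationConfig(n_traj=500, n_points=200, dt=0.1, loc_sigma=0.0, seed=202)
    return simulate_brownian(cfg, D=0.1)


@pytest.fixture(scope="session")
def two_state_ensemble():
    """100 two-state trajectories (p_fast=0.5, sigma 0.03/0.10 um), 200 steps."""
    cfg = SimulationConfig(n_traj=100, n_points=201, dt=0.1, seed=303)
    return simulate_two_state(cfg, p_fast=0.5, sigma_slow=0.03, sigma_fast=0.10)


def make_gapped_trajectory(seed: int, n: int = 40, gap_prob: float = 0.25) -> Trajectory:
    """Random-walk trajectory with random interior gaps, for oracle checks."""
    rng = np.random.default_rng(seed)
    xy = np.cumsum(rng.normal(0, 0.1, size=(n, 2)), axis=0)
    gaps = rng.random(n - 2) < gap_prob
    xy[1:-1][gaps] = np.nan
    return Trajectory("g", np.arange(n), xy, 0.1)
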