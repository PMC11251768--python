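import numpy as np
import pytest

from mothnav import config as pinned
from mothnav.navigator import simulate_flight
from mothnav.plume import PlumeConfig, PuffPlume, WindState
from mothnav.segmentation import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def still_wind():
    return WindState(mean_velocity=[0.0, 0.0, 0.0], turbulence_intensity=0.0)


@pytest.fixture
def small_plume():
    cfg = PlumeConfig(source_position=[2.0, 0.0, 0.0], puff_frequency=1.0,
                      initial_spread=0.05, growth_rate=1e-3)
    return PuffPlume(cfg, rng=np.random.default_rng(0))


def make_trajectory(positions, sample_rate=75.0):
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    return Trajectory(times=np.arange(n) / sample_rate, positions=positions,
                      sample_rate=sample_rate)


@pytest.fixture
def straight_line_traj():
    i = np.arange(40.0)
    return make_trajectory(np.column_stack([i, 2 * i, 3 * i]))


def quick_flight(seed=0, **overrides):
    """A short pinned-config flight for smoke tests (capped at 8 s)."""
    agent = pinned.pinned_agent_config(max_flight_time=overrides.pop("max_flight_time", 8.0))
    return simulate_flight(pinned.pinned_plume_config(), pinned.pinned_wind(),
                           agent, pinned.pinned_sensor_config(), seed=seed,
                           start_position=overrides.pop("start_position", (0.0, 0.1, 0.0)),
                           spin_up_time=overrides.pop("spin_up_time", 12.0))
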