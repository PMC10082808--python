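import numpy as np
import pandas as pd
import pytest

from pedscatter import ClassSpec, RunConfig, SimScenario, simulate_dataset
from pedscatter.preprocess import FrameSeries


def make_frame(times, pos, vel, group_speed=None) -> FrameSeries:
    """FrameSeries where rotated and unrotated coordinates coincide
    (group heading along +x) — convenient for direct observable tests."""
    times = np.asarray(times, float)
    pos = np.asarray(pos, float)
    vel = np.asarray(vel, float)
    if group_speed is None:
        group_speed = np.full(len(times), 1.2)
    return FrameSeries(times=times, pos=pos, vel=vel, pos_rel=pos.copy(),
                       vel_rel=vel.copy(), group_speed=group_speed)


def straight_walker(x0, y0, vx, vy, t0=0.0, t1=8.0, dt=0.05, pid="p"):
    """DataFrame trajectory of a constant-velocity pedestrian."""
    t = np.arange(t0, t1 + dt / 2, dt)
    return pd.DataFrame({
        "time": t, "id": pid, "x": x0 + vx * (t - t0), "y": y0 + vy * (t - t0),
    })


@pytest.fixture(scope="session")
def null_dataset():
    """No repulsion, no noise: relative motion is exactly straight."""
    spec = ClassSpec("null", 0.7, 0.0, potential_strength=0.0,
                     intrusion_propensity=0.0)
    scenario = SimScenario(n_encounters=60, position_noise_sd=0.0)
    return simulate_dataset(scenario, [spec], seed=42)


@pytest.fixture(scope="session")
def small_dataset():
    """Modest noisy dataset with two classes for pipeline-level tests."""
    specs = [
        ClassSpec("loose", 0.8, 0.1, potential_strength=0.2,
                  intrusion_propensity=0.2),
        ClassSpec("tight", 0.6, 0.08, potential_strength=0.8,
                  intrusion_propensity=0.03),
    ]
    scenario = SimScenario(n_encounters=120, position_noise_sd=0.01,
                           class_mix={"loose": 0.5, "tight": 0.5})
    return simulate_dataset(scenario, specs, seed=7)


@pytest.fixture()
def config():
    return RunConfig()
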