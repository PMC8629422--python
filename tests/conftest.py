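import numpy as np
import pytest

import surgecast as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plume_config():
    return sc.PlumeConfig()


@pytest.fixture
def straight_plume():
    """Deterministic plume: no meander, no scatter -- puffs ride the x axis."""
    return sc.PlumeConfig(meander_sigma=0.0, puff_scatter_sigma=0.0, meander_tau=1.0)


class ScriptedController:
    """Drives a constant motor command; ignores all sensory input."""

    def __init__(self, v=0.0, omega=0.0):
        self.cmd = sc.MotorCommand(v, omega)

    def reset(self, rng, start_time=0.0):
        pass

    def command(self, now, heading, left_hit, right_hit, wind_vector):
        return self.cmd


@pytest.fixture
def scripted_controller_factory():
    return ScriptedController


def make_trialset(paths, plume_config=None, trial_config=None, outcomes=None):
    """Build a TrialSet from raw (x, y[, heading]) sample arrays."""
    import pandas as pd

    plume_config = plume_config or sc.PlumeConfig()
    trial_config = trial_config or sc.TrialConfig()
    trajectories = []
    for i, arr in enumerate(paths):
        arr = np.asarray(arr, dtype=float)
        n = len(arr)
        df = pd.DataFrame(
            {
                "time_s": np.arange(n) * trial_config.dt,
                "x_mm": arr[:, 0],
                "y_mm": arr[:, 1],
                "heading_rad": arr[:, 2] if arr.shape[1] > 2 else np.zeros(n),
                "v_mms": np.zeros(n),
                "omega_rads": np.zeros(n),
                "left_hit": np.zeros(n, dtype=bool),
                "right_hit": np.zeros(n, dtype=bool),
                "f_hz": np.zeros(n),
                "matched": np.zeros(n, dtype=bool),
            }
        )
        outcome = outcomes[i] if outcomes else "failure"
        st = float(df.time_s.iloc[-1]) if outcome == "success" else None
        trajectories.append(sc.Trajectory(df, outcome, st, seed=i))
    return sc.TrialSet(trajectories, plume_config, trial_config)


@pytest.fixture
def trialset_builder():
    return make_trialset
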