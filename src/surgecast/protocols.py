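"""Measurement protocols for the model's checkable quantities.

Each function runs a small, fully specified experiment against the public
API and returns the measured quantity: the surge-phase duration of the
motor program, the casting controller's post-loss hold distance, the gain
breakpoints, and the three-algorithm comparison experiment.  The
acceptance script and the test suite both drive these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .controllers import (
    CastingController,
    MiM2Params,
    MiM2State,
    _logistic,
    make_controller,
    mim2_command,
)
from .plume import PlumeConfig
from .sensing import AgentPose
from .simulator import TrialConfig, run_batch, step_kinematics
from .stats import fisher_exact, steel_dwass

__all__ = [
    "surge_phase_duration",
    "casting_loss_distance",
    "gain_breakpoint",
    "ComparisonResult",
    "comparison_experiment",
]

SCENARIOS = {
    "center": [(300.0, 0.0)],
    "offset": [(300.0, 100.0), (300.0, -100.0)],
}
CONTROLLERS = ("mim2", "surge_zigzag", "casting")


def surge_phase_duration(
    params: MiM2Params | None = None, f: float = 0.2, grid: float = 0.001
) -> float:
    """Duration of straight motion after one isolated detection onset.

    The controller is driven with a single detection at t_d = 0 (matched
    wind, low frequency) and its two logistic weights are sampled on a
    millisecond grid; the surge ends when the zigzag weight first exceeds
    the surge weight.
    """
    p = params if params is not None else MiM2Params()
    state = MiM2State(t_d=0.0, rd0=+1, f=f, matched=True)
    taus = np.arange(0.0, 3.0, grid)
    for tau in taus:
        switch = p.gamma * (tau - p.beta)
        if _logistic(-switch) > _logistic(switch):
            # sanity: the motor output at this instant is indeed a turn
            cmd = mim2_command(state, float(tau), p)
            assert abs(cmd.omega) > p.omega0 / 2
            return float(tau)
    raise RuntimeError("zigzag phase never started")  # pragma: no cover


def casting_loss_distance(dt: float = 0.01, seed: int = 0) -> float:
    """Path length (mm) the casting agent holds its heading after plume loss.

    The agent tracks inside a plume band (both antennae driven) for 2 s,
    then all odor is removed; the distance traveled between the loss and
    the first crosswind (cast-mode) command is measured from the
    integrated trajectory.
    """
    ctrl = CastingController()
    ctrl.reset(np.random.default_rng(seed))
    wind = (100.0, 0.0)
    pose = AgentPose(300.0, 0.0, math.pi)
    t = 0.0
    for _ in range(int(2.0 / dt)):  # in-band tracking
        cmd = ctrl.command(t, pose.heading, True, True, wind)
        pose = step_kinematics(pose, cmd, dt)
        t += dt
    assert ctrl.mode == "track"
    # plume removed: hold, then cast
    loss_pose = None
    path = 0.0
    for _ in range(int(10.0 / dt)):
        cmd = ctrl.command(t, pose.heading, False, False, wind)
        if loss_pose is None:
            loss_pose = pose  # mode just flipped to "hold"
        if ctrl.mode == "cast":
            return path
        new = step_kinematics(pose, cmd, dt)
        path += math.hypot(new.x - pose.x, new.y - pose.y)
        pose = new
        t += dt
    raise RuntimeError("casting mode never engaged")  # pragma: no cover


def gain_breakpoint(channel: str, matched: bool = True,
                    params: MiM2Params | None = None) -> float:
    """Frequency (Hz) where K(f) switches from increasing to decreasing.

    Evaluates the piecewise-linear gain on f in [0, 1.2] at 0.01 Hz steps
    and locates the sign change of the successive differences.
    """
    p = params if params is not None else MiM2Params()
    gain = p.gains.gain(channel, matched)
    fs = np.round(np.arange(0.0, 1.2001, 0.01), 10)
    ks = np.array([gain(f) for f in fs])
    d = np.diff(ks)
    increasing = d > 1e-12
    decreasing = d < -1e-12
    idx = np.flatnonzero(increasing[:-1] & decreasing[1:])
    if idx.size != 1:  # pragma: no cover - malformed table
        raise ValueError("gain has no unique increasing-to-decreasing switch")
    return float(fs[idx[0] + 1])


@dataclass
class ComparisonResult:
    """Outcome of the three-algorithm comparison experiment."""

    n: int
    success: dict = field(default_factory=dict)  # (scenario, name) -> count
    search_times: dict = field(default_factory=dict)  # (scenario, name) -> array
    fisher_p: dict = field(default_factory=dict)  # (scenario, baseline) -> p
    mim2_is_larger: dict = field(default_factory=dict)
    steel_dwass_p: np.ndarray | None = None  # pooled scenarios, CONTROLLERS order

    @property
    def max_fisher_p(self) -> float:
        return max(self.fisher_p.values())

    @property
    def casting_pairwise_max_p(self) -> float:
        i = CONTROLLERS.index("casting")
        others = [j for j in range(len(CONTROLLERS)) if j != i]
        return float(max(self.steel_dwass_p[i, j] for j in others))

    def casting_median_is_minimum(self) -> bool:
        med = {
            name: np.median(np.concatenate(
                [self.search_times[(scen, name)] for scen in SCENARIOS]))
            for name in CONTROLLERS
        }
        return med["casting"] == min(med.values())


def comparison_experiment(
    n: int = 300,
    base_seed: int = 0,
    plume: PlumeConfig | None = None,
    trial: TrialConfig | None = None,
) -> ComparisonResult:
    """Run the algorithm-comparison experiment at ``n`` trials per batch.

    Each controller runs ``n`` trials from the center start (300, 0) and
    ``n`` alternating between the crosswind offsets (300, +-100), 300 s
    limit, 10 mm success radius.  MiM2's success count is Fisher-tested
    against each baseline per scenario, and the pooled successful search
    times are compared across controllers with the Steel--Dwass test.
    """
    plume = plume if plume is not None else PlumeConfig()
    trial = trial if trial is not None else TrialConfig(record=False)
    res = ComparisonResult(n=n)
    for scen, starts in SCENARIOS.items():
        for name in CONTROLLERS:
            controller = make_controller(name)
            ts = run_batch(plume, controller, trial, n, base_seed, starts)
            res.success[(scen, name)] = ts.success_count
            res.search_times[(scen, name)] = ts.search_times
        for baseline in ("surge_zigzag", "casting"):
            a = res.success[(scen, "mim2")]
            b = res.success[(scen, baseline)]
            table = np.array([[a, n - a], [b, n - b]])
            res.fisher_p[(scen, baseline)] = fisher_exact(table)
            res.mim2_is_larger[(scen, baseline)] = a > b
    groups = [
        np.concatenate([res.search_times[(scen, name)] for scen in SCENARIOS])
        for name in CONTROLLERS
    ]
    res.steel_dwass_p = steel_dwass(groups)
    return res
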