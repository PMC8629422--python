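"""Trial execution: non-holonomic kinematics, single trials, seeded batches.

The agent is a unicycle (no lateral slip): each tick the plume advances,
the antennae are sampled, the controller converts the sensory state into a
(v, omega) motor command, and the pose integrates heading-first.  A trial
succeeds the first time the agent comes within ``success_radius`` of the
odor source and fails when the time limit elapses.

Trials are fully seeded: the plume and the controller draw from
independent streams spawned from the trial seed, so a (config, seed) pair
reproduces a trajectory exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .controllers import MotorCommand
from .plume import PlumeConfig, PlumeState, step_plume, wind_at
from .sensing import AgentPose, AntennaGeometry, wrap_angle

__all__ = [
    "TrialConfig",
    "Trajectory",
    "TrialSet",
    "step_kinematics",
    "run_trial",
    "run_batch",
]

_LOG_COLUMNS = (
    "time_s",
    "x_mm",
    "y_mm",
    "heading_rad",
    "v_mms",
    "omega_rads",
    "left_hit",
    "right_hit",
    "f_hz",
    "matched",
)


@dataclass(frozen=True)
class TrialConfig:
    dt: float = 0.01  # s; the gamma=1000 surge/zigzag switch spans ~0.01 s
    time_limit: float = 300.0  # s
    success_radius: float = 10.0  # mm, closed ball around the source
    start_position: tuple[float, float] = (300.0, 0.0)  # mm
    start_heading: float = math.pi  # rad; facing upwind by default
    seed: int = 0
    boundary_mode: str = "clamp"
    warmup: float = 5.0  # s of plume evolution before the agent starts
    antenna: AntennaGeometry = field(default_factory=AntennaGeometry)
    record: bool = True  # keep per-tick samples (False: outcome only)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.time_limit <= 0 or self.success_radius <= 0:
            raise ValueError("dt, time_limit and success_radius must be > 0")
        if self.boundary_mode != "clamp":
            raise ValueError("boundary_mode must be 'clamp'")


@dataclass
class Trajectory:
    """One trial: per-tick samples, the outcome, and the seed that made it."""

    samples: pd.DataFrame
    outcome: str  # "success" | "failure"
    search_time: float | None  # s, defined for successes
    seed: int

    @property
    def success(self) -> bool:
        return self.outcome == "success"

    def to_csv(self, path) -> None:
        self.samples.to_csv(path, index=False)


@dataclass
class TrialSet:
    """A batch of trajectories plus the configuration that produced them."""

    trajectories: list[Trajectory]
    plume_config: PlumeConfig
    trial_config: TrialConfig

    @property
    def n(self) -> int:
        return len(self.trajectories)

    @property
    def success_count(self) -> int:
        return sum(t.success for t in self.trajectories)

    @property
    def search_times(self) -> np.ndarray:
        return np.array([t.search_time for t in self.trajectories if t.success])


def step_kinematics(pose: AgentPose, cmd: MotorCommand, dt: float) -> AgentPose:
    """Unicycle update, heading first.

    The motor command's omega is rightward(clockwise)-positive, so the
    counterclockwise-positive world heading integrates theta_dot = -omega.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    theta = wrap_angle(pose.heading - cmd.omega * dt)
    return AgentPose(
        pose.x + cmd.v * math.cos(theta) * dt,
        pose.y + cmd.v * math.sin(theta) * dt,
        theta,
    )


def run_trial(plume_config: PlumeConfig, controller, trial_config: TrialConfig) -> Trajectory:
    """Run one odor-source search trial.

    The plume is warmed up for ``trial_config.warmup`` seconds before the
    agent is placed; trial time starts at 0 at the end of the warm-up.
    Success is declared at the first sample within ``success_radius`` of
    the source (closed ball); otherwise the trial fails at the time limit.
    The agent is clamped to the field bounds.
    """
    cfg = trial_config
    seq = np.random.SeedSequence(cfg.seed)
    plume_rng, ctrl_rng = [np.random.default_rng(s) for s in seq.spawn(2)]

    plume = PlumeState(rng=plume_rng)
    dt = cfg.dt
    for _ in range(int(round(cfg.warmup / dt))):
        step_plume(plume, plume_config, dt)

    controller.reset(ctrl_rng, start_time=0.0)
    wind = wind_at(plume_config)
    sx, sy = plume_config.source_position
    xmin, xmax, ymin, ymax = plume_config.field_bounds
    lat = cfg.antenna.lateral_offset
    ant = cfg.antenna.anterior_offset
    r2_success = cfg.success_radius**2

    n_steps = int(round(cfg.time_limit / dt))
    if cfg.record:
        log = np.empty((n_steps + 1, len(_LOG_COLUMNS)))
    else:
        log = None

    x, y = cfg.start_position
    theta = wrap_angle(cfg.start_heading)
    command = controller.command  # cache hot attributes
    outcome, search_time = "failure", None
    t = 0.0
    k = 0

    # hoisted plume-detection locals (keep the hot loop allocation-free)
    px, py, pr = plume.puff_x, plume.puff_y, plume.puff_r

    for k in range(n_steps + 1):
        # sense both antennae directly against the puff lists
        ch, sh = math.cos(theta), math.sin(theta)
        hx, hy = x + ant * ch, y + ant * sh
        lx, ly = hx - lat * sh, hy + lat * ch
        rx, ry = hx + lat * sh, hy - lat * ch
        left_hit = right_hit = False
        for i in range(len(px)):
            cx, cy, r = px[i], py[i], pr[i]
            rr = r * r
            if not left_hit:
                dx, dy = lx - cx, ly - cy
                left_hit = dx * dx + dy * dy <= rr
            if not right_hit:
                dx, dy = rx - cx, ry - cy
                right_hit = dx * dx + dy * dy <= rr
            if left_hit and right_hit:
                break

        cmd = command(t, theta, left_hit, right_hit, wind)

        if log is not None:
            state = getattr(controller, "state", None)
            row = log[k]
            row[0] = t
            row[1] = x
            row[2] = y
            row[3] = theta
            row[4] = cmd.v
            row[5] = cmd.omega
            row[6] = left_hit
            row[7] = right_hit
            row[8] = getattr(state, "f", 0.0)
            row[9] = getattr(state, "matched", False)

        dx, dy = x - sx, y - sy
        if dx * dx + dy * dy <= r2_success:
            outcome, search_time = "success", t
            break
        if k == n_steps:
            break

        # integrate pose (heading first), clamp to the arena walls
        theta = theta - cmd.omega * dt
        if theta > math.pi or theta <= -math.pi:
            theta = wrap_angle(theta)
        x += cmd.v * math.cos(theta) * dt
        y += cmd.v * math.sin(theta) * dt
        if x < xmin:
            x = xmin
        elif x > xmax:
            x = xmax
        if y < ymin:
            y = ymin
        elif y > ymax:
            y = ymax

        step_plume(plume, plume_config, dt)
        px, py, pr = plume.puff_x, plume.puff_y, plume.puff_r
        t += dt

    if log is not None:
        df = pd.DataFrame(log[: k + 1], columns=_LOG_COLUMNS)
        df["left_hit"] = df["left_hit"].astype(bool)
        df["right_hit"] = df["right_hit"].astype(bool)
        df["matched"] = df["matched"].astype(bool)
    else:
        df = pd.DataFrame(columns=_LOG_COLUMNS)
    return Trajectory(df, outcome, search_time, cfg.seed)


def run_batch(
    plume_config: PlumeConfig,
    controller,
    trial_config: TrialConfig,
    n: int,
    base_seed: int = 0,
    start_positions: Sequence[tuple[float, float]] | None = None,
) -> TrialSet:
    """Run ``n`` independent trials with seeds ``base_seed + i``.

    ``start_positions`` cycles over trials (e.g. ``[(300, 100), (300, -100)]``
    alternates the two crosswind start offsets); by default every trial
    starts at ``trial_config.start_position``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    trajectories = []
    for i in range(n):
        cfg = replace(trial_config, seed=base_seed + i)
        if start_positions is not None:
            cfg = replace(cfg, start_position=tuple(start_positions[i % len(start_positions)]))
        trajectories.append(run_trial(plume_config, controller, cfg))
    return TrialSet(trajectories, plume_config, trial_config)
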