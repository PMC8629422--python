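"""Behavior-generation algorithms: MiM2 and the surge-zigzag / casting baselines.

MiM2 (multisensory input-based motor modulation) extends the classical
surge-zigzagging reflex of the walking male silkmoth with wind and vision
channels.  After each odor detection at time t_d the controller emits a
straight *surge* that decays over ~0.5 s, then an alternating sequence of
*zigzag* turns that saturates into one-directional *looping*:

    v(t)     = K_v(f) * exp(-tau) / (1 + exp(gamma * (tau - beta)))
    omega(t) = omega0 * Rd(0) / (1 + exp(gamma * (tau - beta)))
             + K_omega(f) * Rd(N) / (1 + exp(-gamma * (tau - beta)))

with tau = t - t_d.  The steep logistic (gamma = 1000) switches between the
surge term and the turn term at tau = beta = 0.5 s.  K_v and K_omega are
piecewise-linear gains in the odor-detection frequency f, with separate
tables for the matched (odor side = wind side) and mismatched conditions;
Rd(0) is the detected side (-1 left, +1 right) and Rd(N) alternates with
the turn counter

    N(tau) = floor(0.0116 tau^3 - 0.199 tau^2 + 1.1971 tau + 0.4482),

clamped to [0, 3].  A vision "equalizer" scales leftward and rightward
turn commands independently (both 1 under veridical optic flow).

Sign convention: positive omega is a rightward (clockwise) turn, matching
Rd = +1 for a right-antenna detection; the kinematics layer integrates
theta_dot = -omega in the counterclockwise-positive world frame.

The two baselines share the plumbing: surge-zigzagging is the constant-gain
ablation of MiM2 (no wind, no frequency modulation), and casting is the
flying-moth strategy mapped to the plane -- upwind at a fixed offset angle
while in the plume, hold for d_lost after losing it, then crosswind sweeps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .sensing import (
    FrequencyCounter,
    Side,
    compare,
    discriminate_direction,
    hits_to_side,
    perceive_wind,
    wrap_angle,
)

__all__ = [
    "MotorCommand",
    "PiecewiseGain",
    "GainTable",
    "default_gain_table",
    "printed_gain_table",
    "MiM2Params",
    "MiM2State",
    "mim2_gain",
    "turn_number",
    "mim2_command",
    "mim2_on_detection",
    "SurgeZigzagParams",
    "surge_zigzag_command",
    "CastingParams",
    "CastingState",
    "casting_command",
    "MiM2Controller",
    "SurgeZigzagController",
    "CastingController",
    "make_controller",
]

# Turn-counter cubic in tau = t - t_d (dimensionless coefficients fitted to
# observed zigzag timing); N = floor(cubic), clamped to [0, n_cap].
_N_C3, _N_C2, _N_C1, _N_C0 = 0.0116, -0.199, 1.1971, 0.4482

_EXP_CLAMP = 500.0  # gamma = 1000 overflows naive exp()


def _logistic(x: float) -> float:
    """1 / (1 + exp(x)) with the exponent clamped to +-500."""
    if x > _EXP_CLAMP:
        x = _EXP_CLAMP
    elif x < -_EXP_CLAMP:
        x = -_EXP_CLAMP
    return 1.0 / (1.0 + math.exp(x))


class MotorCommand(NamedTuple):
    v: float  # mm/s, >= 0
    omega: float  # rad/s, rightward(clockwise)-positive


@dataclass(frozen=True)
class PiecewiseGain:
    """K(f) = a*f + b on each side of a frequency breakpoint, floored at 0."""

    a_low: float
    b_low: float
    a_high: float
    b_high: float
    breakpoint: float  # Hz; low branch applies for f <= breakpoint

    def __call__(self, f: float) -> float:
        if f <= self.breakpoint:
            value = self.a_low * f + self.b_low
        else:
            value = self.a_high * f + self.b_high
        return value if value > 0.0 else 0.0


@dataclass(frozen=True)
class GainTable:
    """Piecewise-linear gains per channel (v, omega) and match condition."""

    v_matched: PiecewiseGain
    v_mismatched: PiecewiseGain
    omega_matched: PiecewiseGain
    omega_mismatched: PiecewiseGain

    def gain(self, channel: str, matched: bool) -> PiecewiseGain:
        if channel == "v":
            return self.v_matched if matched else self.v_mismatched
        if channel in ("omega", "w"):
            return self.omega_matched if matched else self.omega_mismatched
        raise ValueError(f"unknown channel {channel!r}")


def default_gain_table() -> GainTable:
    """Fitted gain coefficients (v in mm/s, omega in rad/s).

    The mismatched angular gain uses a 0.2 Hz breakpoint -- where its two
    fitted lines actually intersect and where the behavioral peak sits --
    rather than the 0.4 Hz row split of the printed coefficient table;
    see :func:`printed_gain_table` for the literal variant.
    """
    return GainTable(
        v_matched=PiecewiseGain(5.36, 12.9, -11.4, 24.6, 0.7),
        v_mismatched=PiecewiseGain(0.0, 10.5, 0.0, 10.5, 0.7),
        omega_matched=PiecewiseGain(0.638, 1.40, -1.22, 2.16, 0.4),
        omega_mismatched=PiecewiseGain(0.870, 1.42, -0.997, 1.80, 0.2),
    )


def printed_gain_table() -> GainTable:
    """Gain table with the mismatched angular breakpoint at 0.4 Hz as printed."""
    base = default_gain_table()
    return replace(
        base,
        omega_mismatched=replace(base.omega_mismatched, breakpoint=0.4),
    )


@dataclass(frozen=True)
class MiM2Params:
    gamma: float = 1000.0  # logistic sharpness of the surge/zigzag switch
    beta: float = 0.50  # s, surge duration
    omega0: float = 0.57  # rad/s, surge-phase turn rate toward the odor side
    n_cap: int = 3  # zigzag turns saturate into looping at N = 3
    gains: GainTable = field(default_factory=default_gain_table)
    vision_gains: tuple[float, float] = (1.0, 1.0)  # (g_left, g_right)
    frequency_window: float = 5.0  # s, sliding window of the f counter

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.beta <= 0:
            raise ValueError("gamma and beta must be > 0")


@dataclass(frozen=True)
class MiM2State:
    """Latched sensory state between detection onsets."""

    t_d: float = 0.0  # s, last detection time
    rd0: int = 1  # detected side at t_d: -1 left, +1 right
    f: float = 0.0  # Hz, frequency latched at the last onset
    matched: bool = False  # comparator flag latched at the last onset


def mim2_gain(f: float, matched: bool, channel: str, params: MiM2Params) -> float:
    """Evaluate the piecewise-linear gain K_channel(f) for one condition."""
    if f < 0:
        raise ValueError("f must be >= 0")
    return params.gains.gain(channel, matched)(f)


def turn_number(dt_since_detection: float, n_cap: int = 3) -> int:
    """Turn counter N: floor of the timing cubic, clamped to [0, n_cap]."""
    tau = dt_since_detection
    if tau < 0:
        raise ValueError("dt_since_detection must be >= 0")
    n = math.floor(((_N_C3 * tau + _N_C2) * tau + _N_C1) * tau + _N_C0)
    if n < 0:
        return 0
    return n_cap if n > n_cap else n


def _rd_of_turn(rd0: int, n: int) -> int:
    """Turn direction Rd(N): first zigzag toward the detected side, then
    alternating; looping (N at cap) keeps the last direction."""
    if n <= 0:
        return rd0
    return rd0 if n % 2 == 1 else -rd0


def mim2_command(
    state: MiM2State,
    now: float,
    params: MiM2Params,
    vision_gains: tuple[float, float] | None = None,
) -> MotorCommand:
    """Motor output of the MiM2 controller at time ``now``."""
    g_left, g_right = vision_gains if vision_gains is not None else params.vision_gains
    tau = now - state.t_d
    switch = params.gamma * (tau - params.beta)
    surge_weight = _logistic(switch)  # ~1 during the surge, ~0 after
    zigzag_weight = _logistic(-switch)

    k_v = params.gains.gain("v", state.matched)(state.f)
    v = k_v * math.exp(-tau if tau < _EXP_CLAMP else _EXP_CLAMP) * surge_weight

    n = turn_number(tau, params.n_cap)
    k_w = params.gains.gain("omega", state.matched)(state.f)
    omega = (
        params.omega0 * state.rd0 * surge_weight
        + k_w * _rd_of_turn(state.rd0, n) * zigzag_weight
    )
    omega *= g_left if omega < 0 else g_right
    return MotorCommand(v, omega)


def mim2_on_detection(
    state: MiM2State,
    time: float,
    side: Side,
    f: float,
    matched: bool,
    rng: np.random.Generator,
) -> MiM2State:
    """State transition at a detection onset: restart the surge and latch
    the detected side, frequency, and comparator flag."""
    rd0 = discriminate_direction(side is not Side.RIGHT, side is not Side.LEFT, rng)
    return MiM2State(t_d=time, rd0=rd0, f=f, matched=matched)


@dataclass(frozen=True)
class SurgeZigzagParams:
    """Constant-gain ablation of MiM2: olfaction only, no frequency or wind
    modulation.  Defaults are the matched-condition zero-frequency gains so
    the algorithm is the exact zero-slope ablation of the full model."""

    v_const: float = 12.9  # mm/s
    omega_const: float = 1.40  # rad/s
    surge_duration: float = 0.50  # s
    gamma: float = 1000.0
    omega0: float = 0.57
    n_cap: int = 3

    def __post_init__(self) -> None:
        if self.surge_duration <= 0:
            raise ValueError("surge_duration must be > 0")


def surge_zigzag_command(
    state: MiM2State, now: float, params: SurgeZigzagParams
) -> MotorCommand:
    """Motor output of the surge-zigzagging baseline (written out directly,
    not delegated to :func:`mim2_command`, so the ablation-equivalence
    property is a real cross-check)."""
    tau = now - state.t_d
    switch = params.gamma * (tau - params.surge_duration)
    surge_weight = _logistic(switch)
    v = params.v_const * math.exp(-tau if tau < _EXP_CLAMP else _EXP_CLAMP) * surge_weight
    n = turn_number(tau, params.n_cap)
    omega = params.omega0 * state.rd0 * surge_weight + params.omega_const * _rd_of_turn(
        state.rd0, n
    ) * _logistic(-switch)
    return MotorCommand(v, omega)


@dataclass(frozen=True)
class CastingParams:
    """Casting baseline: upwind at a fixed offset while in the plume,
    hold the heading for d_lost after losing it, then crosswind sweeps."""

    beta_offset: float = 30.0  # deg, offset from upwind while tracking
    d_lost: float = 25.0  # mm, path length to hold heading after plume loss
    v_const: float = 12.9  # mm/s
    cast_span: float = 100.0  # mm, crosswind leg length before reversing
    steering_gain: float = 5.0  # 1/s, proportional heading controller
    omega_max: float = 3.0  # rad/s, steering saturation

    def __post_init__(self) -> None:
        if not 0 < self.beta_offset < 90:
            raise ValueError("beta_offset must be in (0, 90) degrees")
        if self.d_lost <= 0:
            raise ValueError("d_lost must be > 0")


@dataclass(frozen=True)
class CastingState:
    """Discrete state of the casting machine.

    mode: ``track`` (in plume), ``hold`` (just lost, keep heading), or
    ``cast`` (crosswind sweep).  Signs follow the odor-side convention:
    -1 = left, +1 = right.
    """

    mode: str = "cast"
    offset_sign: int = 1  # side of the upwind beta offset while tracking
    cast_sign: int = 1  # side of the current crosswind leg
    hold_heading: float = 0.0  # heading latched at plume loss


def casting_command(
    state: CastingState, heading: float, wind_vector, params: CastingParams
) -> MotorCommand:
    """Motor output of the casting baseline for a given machine state.

    Tracking steers ``beta_offset`` degrees off upwind toward the last
    detected side; holding keeps the latched heading; casting steers
    90 deg off upwind.  omega is a saturated proportional command toward
    the target heading; v is constant.
    """
    p = params
    upwind = math.atan2(-float(wind_vector[1]), -float(wind_vector[0]))
    if state.mode == "track":
        # offset_sign = -1 steers beta_offset to the left of upwind
        target = upwind + (-state.offset_sign) * math.radians(p.beta_offset)
    elif state.mode == "hold":
        target = state.hold_heading
    else:
        target = upwind + (-state.cast_sign) * (math.pi / 2.0)
    err = wrap_angle(target - heading)  # desired CCW heading change
    omega = -p.steering_gain * err  # rightward-positive command
    if omega > p.omega_max:
        omega = p.omega_max
    elif omega < -p.omega_max:
        omega = -p.omega_max
    return MotorCommand(p.v_const, omega)


# ---------------------------------------------------------------------------
# Stateful controller wrappers used by the simulator.  Each exposes
#   reset(rng) and command(now, heading, left_hit, right_hit, wind_vector)
# and keeps its own onset bookkeeping.
# ---------------------------------------------------------------------------


class MiM2Controller:
    """Stateful wrapper: onset detection, frequency counter, comparator and
    the MiM2 motor map."""

    name = "mim2"

    def __init__(self, params: MiM2Params | None = None):
        self.params = params if params is not None else MiM2Params()
        self.reset(np.random.default_rng(0))

    def reset(self, rng: np.random.Generator, start_time: float = 0.0) -> None:
        self.rng = rng
        self.counter = FrequencyCounter(self.params.frequency_window)
        self._prev_hit = False
        # Virtual detection at trial start: the motor equations need a
        # defined t_d; a random side with f = 0 and no match yields a slow
        # initial surge followed by exploratory looping.
        self.state = MiM2State(
            t_d=start_time, rd0=int(self.rng.choice((-1, 1))), f=0.0, matched=False
        )

    def command(
        self,
        now: float,
        heading: float,
        left_hit: bool,
        right_hit: bool,
        wind_vector,
    ) -> MotorCommand:
        # A detection onset is a false-to-true transition of the combined
        # antennal signal: one onset per odor pulse reaching the moth, so
        # the counted frequency tracks the (1 Hz ceiling) release rate.
        hit = left_hit or right_hit
        if hit and not self._prev_hit:
            self.counter.add(now)
            f = self.counter.rate(now)
            side = hits_to_side(left_hit, right_hit)
            percept = perceive_wind(wind_vector, heading)
            matched = compare(side, percept).matched
            self.state = mim2_on_detection(self.state, now, side, f, matched, self.rng)
        self._prev_hit = hit
        return mim2_command(self.state, now, self.params)


class SurgeZigzagController:
    """Stateful wrapper for the olfaction-only surge-zigzagging baseline."""

    name = "surge_zigzag"

    def __init__(self, params: SurgeZigzagParams | None = None):
        self.params = params if params is not None else SurgeZigzagParams()
        self.reset(np.random.default_rng(0))

    def reset(self, rng: np.random.Generator, start_time: float = 0.0) -> None:
        self.rng = rng
        self._prev_hit = False
        self.state = MiM2State(t_d=start_time, rd0=int(self.rng.choice((-1, 1))))

    def command(
        self,
        now: float,
        heading: float,
        left_hit: bool,
        right_hit: bool,
        wind_vector,
    ) -> MotorCommand:
        hit = left_hit or right_hit
        if hit and not self._prev_hit:
            rd0 = discriminate_direction(left_hit, right_hit, self.rng)
            self.state = MiM2State(t_d=now, rd0=rd0)
        self._prev_hit = hit
        return surge_zigzag_command(self.state, now, self.params)


class CastingController:
    """Casting baseline with an explicit track / hold / cast state machine.

    Modes: ``track`` (in plume, steer upwind +- beta_offset toward the last
    detected side), ``hold`` (plume lost, keep heading until d_lost mm
    traveled), ``cast`` (steer crosswind, reversing side every cast_span mm
    without a re-detection).  Before the first detection the agent casts
    immediately -- the classic plume-finding sweep.
    """

    name = "casting"

    def __init__(self, params: CastingParams | None = None):
        self.params = params if params is not None else CastingParams()
        self.reset(np.random.default_rng(0))

    def reset(self, rng: np.random.Generator, start_time: float = 0.0) -> None:
        self.rng = rng
        self.state = CastingState(
            mode="cast",
            offset_sign=int(rng.choice((-1, 1))),
            cast_sign=int(rng.choice((-1, 1))),
        )
        self._dist_since_loss = 0.0
        self._dist_in_leg = 0.0
        self._last_time: float | None = None

    @property
    def mode(self) -> str:
        return self.state.mode

    def command(
        self,
        now: float,
        heading: float,
        left_hit: bool,
        right_hit: bool,
        wind_vector,
    ) -> MotorCommand:
        p = self.params
        s = self.state
        dt = 0.0 if self._last_time is None else now - self._last_time
        self._last_time = now
        step_dist = p.v_const * dt

        hit = left_hit or right_hit
        if hit:
            if left_hit and not right_hit:
                offset = -1
            elif right_hit and not left_hit:
                offset = 1
            elif s.mode != "track":
                offset = int(self.rng.choice((-1, 1)))
            else:
                offset = s.offset_sign
            s = replace(s, mode="track", offset_sign=offset)
            self._dist_since_loss = 0.0
            self._dist_in_leg = 0.0
        elif s.mode == "track":
            # Plume just lost: hold the current heading for d_lost.
            s = replace(s, mode="hold", hold_heading=heading)
            self._dist_since_loss = 0.0
        elif s.mode == "hold":
            self._dist_since_loss += step_dist
            if self._dist_since_loss >= p.d_lost:
                s = replace(s, mode="cast", cast_sign=s.offset_sign)
                self._dist_in_leg = 0.0
        else:  # cast
            self._dist_in_leg += step_dist
            if self._dist_in_leg >= p.cast_span:
                s = replace(s, cast_sign=-s.cast_sign)
                self._dist_in_leg = 0.0

        self.state = s
        return casting_command(s, heading, wind_vector, p)


def make_controller(name: str, params=None):
    """Instantiate a controller by its config name."""
    table = {
        "mim2": (MiM2Controller, MiM2Params),
        "surge_zigzag": (SurgeZigzagController, SurgeZigzagParams),
        "casting": (CastingController, CastingParams),
    }
    if name not in table:
        raise ValueError(f"unknown controller {name!r}; expected one of {sorted(table)}")
    cls, _ = table[name]
    return cls(params)
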