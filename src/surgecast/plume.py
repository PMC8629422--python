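"""Synthetic puff-based odor plume in a uniform wind field.

The virtual odor field emulates a 1 Hz point-source release advected by a
uniform left-to-right wind, the same release schedule used for the moth
arena this package models.  Odor is carried in discrete circular *puffs*:
each puff is born at the source, drifts downwind at the wind speed, wanders
crosswind with an Ornstein--Uhlenbeck velocity, and grows linearly in
radius.  An agent senses odor as binary containment in at least one puff,
so the time-averaged detection frequency at a point falls off with distance
from the source -- the cue the search controllers exploit.

Also houses :func:`smoke_mask`, the connected-component luminance filter
used to turn raw smoke-visualization frames into binary plume masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import remove_small_objects

__all__ = [
    "PlumeConfig",
    "Puff",
    "PlumeState",
    "step_plume",
    "detect",
    "wind_at",
    "detection_frequency_map",
    "DetectionFrequencyMap",
    "smoke_mask",
]


@dataclass(frozen=True)
class PlumeConfig:
    """Parameters of the synthetic odor field.

    Lengths are mm, times s, rates Hz.  Defaults are calibrated against
    two field-level conditions of the arena this emulates: the centerline
    detection frequency spans ~1 Hz at the source down to 0.2--0.4 Hz at
    300 mm downwind, and the crosswind-offset start positions (300, +-100)
    sit near the edge of odor reach (~0.1 Hz) rather than fully outside it.
    """

    source_position: tuple[float, float] = (0.0, 0.0)
    emission_rate: float = 1.0  # Hz, one puff per second
    wind_speed: float = 100.0  # mm/s
    wind_direction: tuple[float, float] = (1.0, 0.0)  # unit vector, global frame
    puff_initial_radius: float = 10.0  # mm
    puff_growth_rate: float = 8.0  # mm/s
    meander_sigma: float = 24.0  # mm/s, stationary s.d. of the shared crosswind velocity
    meander_tau: float = 2.0  # s, crosswind velocity correlation time
    puff_scatter_sigma: float = 5.0  # mm/s, independent per-puff crosswind drift s.d.
    field_bounds: tuple[float, float, float, float] = (-150.0, 450.0, -200.0, 200.0)
    # field_bounds is (xmin, xmax, ymin, ymax)

    def __post_init__(self) -> None:
        if self.emission_rate <= 0:
            raise ValueError("emission_rate must be > 0")
        if self.wind_speed < 0:
            raise ValueError("wind_speed must be >= 0")
        if self.puff_initial_radius <= 0:
            raise ValueError("puff_initial_radius must be > 0")
        if self.meander_tau <= 0:
            raise ValueError("meander_tau must be > 0")
        nrm = math.hypot(*self.wind_direction)
        if not math.isclose(nrm, 1.0, rel_tol=1e-6):
            raise ValueError("wind_direction must be a unit vector")
        xmin, xmax, ymin, ymax = self.field_bounds
        sx, sy = self.source_position
        if not (xmin <= sx <= xmax and ymin <= sy <= ymax):
            raise ValueError("source_position must lie inside field_bounds")

    @property
    def crosswind_direction(self) -> tuple[float, float]:
        """Unit vector perpendicular to the wind (90 deg counterclockwise)."""
        wx, wy = self.wind_direction
        return (-wy, wx)


@dataclass(frozen=True)
class Puff:
    """Read-only snapshot of one odor puff at the state's current time."""

    center: tuple[float, float]
    radius: float
    birth_time: float
    crosswind_velocity: float


@dataclass
class PlumeState:
    """Mutable puff field: parallel per-puff lists plus clock and RNG.

    Puffs are stored as plain Python lists because the live population is
    tiny (a handful at the default calibration) and the simulator steps the
    field tens of thousands of times per trial.
    """

    time: float = 0.0
    puff_x: list[float] = field(default_factory=list)
    puff_y: list[float] = field(default_factory=list)
    puff_r: list[float] = field(default_factory=list)
    puff_birth: list[float] = field(default_factory=list)
    puff_vc: list[float] = field(default_factory=list)  # crosswind velocity, mm/s
    meander_velocity: float = 0.0  # shared OU crosswind velocity, mm/s
    n_released: int = 0
    rng: np.random.Generator = field(default_factory=lambda: np.random.default_rng(0))

    @classmethod
    def initial(cls, seed: int | None = 0) -> "PlumeState":
        return cls(rng=np.random.default_rng(seed))

    @property
    def puffs(self) -> list[Puff]:
        return [
            Puff((x, y), r, b, vc)
            for x, y, r, b, vc in zip(
                self.puff_x, self.puff_y, self.puff_r, self.puff_birth, self.puff_vc
            )
        ]

    def __len__(self) -> int:
        return len(self.puff_x)


def step_plume(state: PlumeState, config: PlumeConfig, dt: float) -> PlumeState:
    """Advance the puff field by ``dt`` seconds (in place; returns ``state``).

    Release schedule: puff k is born at time k/emission_rate, k = 1, 2, ...
    (no puff at t = 0); all puffs due in (t, t + dt] are created at the
    source.  Existing puffs advect with the wind plus their own
    Ornstein--Uhlenbeck crosswind velocity (Euler--Maruyama update) and grow
    linearly; puffs whose center leaves the field bounds expanded by their
    radius are culled.

    ``dt`` must be positive and no larger than one emission period so at
    most one puff is released per step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt > 1.0 / config.emission_rate:
        raise ValueError("dt must not exceed one emission period")

    t0 = state.time
    t1 = t0 + dt
    rng = state.rng
    px, py = state.puff_x, state.puff_y
    pr, pvc = state.puff_r, state.puff_vc

    # Shared plume-meander velocity (Ornstein--Uhlenbeck, Euler--Maruyama):
    # the whole ribbon of puffs snakes coherently, as a smoke plume does.
    sigma, tau = config.meander_sigma, config.meander_tau
    vm = state.meander_velocity
    vm += -vm * dt / tau + sigma * math.sqrt(2.0 * dt / tau) * rng.standard_normal()
    state.meander_velocity = vm

    # Advect, meander, grow.
    wx = config.wind_speed * config.wind_direction[0]
    wy = config.wind_speed * config.wind_direction[1]
    cx, cy = config.crosswind_direction
    grow = config.puff_growth_rate * dt
    for i in range(len(px)):
        vc = pvc[i] + vm
        px[i] += (wx + vc * cx) * dt
        py[i] += (wy + vc * cy) * dt
        pr[i] += grow

    # Release puffs due in (t0, t1].
    period = 1.0 / config.emission_rate
    k = state.n_released + 1
    while k * period <= t1 + 1e-12:
        if k * period > t0 + 1e-12:
            px.append(config.source_position[0])
            py.append(config.source_position[1])
            pr.append(config.puff_initial_radius)
            state.puff_birth.append(k * period)
            # stationary draw for the independent per-puff scatter velocity
            pvc.append(config.puff_scatter_sigma * rng.standard_normal())
            state.n_released = k
        k += 1

    # Cull puffs outside the bounds expanded by their radius.
    xmin, xmax, ymin, ymax = config.field_bounds
    keep = [
        i
        for i in range(len(px))
        if (xmin - pr[i] <= px[i] <= xmax + pr[i]) and (ymin - pr[i] <= py[i] <= ymax + pr[i])
    ]
    if len(keep) != len(px):
        state.puff_x = [px[i] for i in keep]
        state.puff_y = [py[i] for i in keep]
        state.puff_r = [pr[i] for i in keep]
        state.puff_birth = [state.puff_birth[i] for i in keep]
        state.puff_vc = [pvc[i] for i in keep]

    state.time = t1
    return state


def detect(state: PlumeState, point: tuple[float, float]) -> bool:
    """True iff ``point`` lies within at least one puff (closed disk)."""
    x, y = point
    px, py, pr = state.puff_x, state.puff_y, state.puff_r
    for i in range(len(px)):
        dx = x - px[i]
        dy = y - py[i]
        r = pr[i]
        if dx * dx + dy * dy <= r * r:
            return True
    return False


def wind_at(config: PlumeConfig, point=None, time: float | None = None) -> np.ndarray:
    """Uniform wind vector (mm/s); independent of position and time."""
    return config.wind_speed * np.asarray(config.wind_direction, dtype=float)


@dataclass(frozen=True)
class DetectionFrequencyMap:
    """Empirical odor-detection-onset frequency (Hz) on a regular grid.

    ``values[ix, iy]`` is the onset rate at cell center
    ``(x_centers[ix], y_centers[iy])``.
    """

    x_centers: np.ndarray
    y_centers: np.ndarray
    values: np.ndarray  # shape (nx, ny), Hz

    def at(self, x: float, y: float) -> float:
        ix = int(np.argmin(np.abs(self.x_centers - x)))
        iy = int(np.argmin(np.abs(self.y_centers - y)))
        return float(self.values[ix, iy])


def detection_frequency_map(
    config: PlumeConfig,
    cell_size: float = 10.0,
    duration: float = 300.0,
    seed: int | None = 0,
    dt: float = 0.05,
    bounds: tuple[float, float, float, float] | None = None,
) -> DetectionFrequencyMap:
    """Simulate the plume and count detection onsets at every grid cell center.

    An onset is a false-to-true transition of :func:`detect` at the cell
    center; the per-cell onset count divided by ``duration`` estimates the
    odor-detection frequency an agent sitting there would experience.
    Durations of at least 60 s are recommended for stable estimates.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    xmin, xmax, ymin, ymax = bounds if bounds is not None else config.field_bounds
    xc = np.arange(xmin + cell_size / 2.0, xmax, cell_size)
    yc = np.arange(ymin + cell_size / 2.0, ymax, cell_size)
    if xc.size == 0 or yc.size == 0:
        raise ValueError("degenerate grid: no cells inside bounds")

    gx, gy = np.meshgrid(xc, yc, indexing="ij")
    gx = gx.ravel()
    gy = gy.ravel()
    onsets = np.zeros(gx.size, dtype=np.int64)
    prev = np.zeros(gx.size, dtype=bool)

    state = PlumeState.initial(seed)
    n_steps = int(round(duration / dt))
    for _ in range(n_steps):
        step_plume(state, config, dt)
        if state.puff_x:
            px = np.asarray(state.puff_x)
            py = np.asarray(state.puff_y)
            pr = np.asarray(state.puff_r)
            d2 = (gx[:, None] - px) ** 2 + (gy[:, None] - py) ** 2
            cur = (d2 <= pr**2).any(axis=1)
        else:
            cur = np.zeros(gx.size, dtype=bool)
        onsets += cur & ~prev
        prev = cur

    values = (onsets / duration).reshape(xc.size, yc.size)
    return DetectionFrequencyMap(xc, yc, values)


def smoke_mask(image: np.ndarray, luminance_threshold: float, min_area: int) -> np.ndarray:
    """Binary plume mask from a grayscale smoke-visualization frame.

    Pixels above ``luminance_threshold`` are kept, then connected
    components (8-connectivity) with area below ``min_area`` pixels are
    discarded as specks.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2D grayscale array")
    binary = image > luminance_threshold
    if min_area <= 1 or not binary.any():
        return binary
    # drop components with area < min_area (max_size removes area <= value)
    return remove_small_objects(binary, max_size=min_area - 1, connectivity=2)
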