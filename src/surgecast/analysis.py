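"""Trajectory analytics: migration probability maps, earth mover's distance,
heading histograms, success metrics and the piecewise-linear gain fit.

The migration probability map discretizes the arena into square cells and
records, per cell, the fraction of trials whose trajectory entered it
(each trial contributes 0 or 1 per cell, however often it revisits).  Two
such maps are compared with the earth mover's distance -- the minimal cost
of morphing one unit-mass cell histogram into the other, with Euclidean
distance between cell centers as the ground metric -- computed as an exact
optimal-transport linear program.

``fit_piecewise_gain`` recovers the two-segment linear speed-vs-frequency
relationship from binned behavioral (or simulated) data; it is the same
least-squares construction that produced the controller gain tables, so
running it on simulated trajectories closes a parameter-recovery loop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from .simulator import TrialSet

__all__ = [
    "MigrationMap",
    "HeadingHistogram",
    "Metrics",
    "migration_map",
    "emd",
    "heading_histogram",
    "metrics",
    "fit_piecewise_gain",
    "PiecewiseFit",
    "recover_speed_gain",
]


@dataclass(frozen=True)
class MigrationMap:
    """Per-cell pass probability P(x, y) over a trial set.

    ``values[ix, iy]`` is the fraction of trials that entered the cell
    whose lower-left corner is ``(origin[0] + ix*cell_size,
    origin[1] + iy*cell_size)``.
    """

    origin: tuple[float, float]  # mm, lower-left corner of cell (0, 0)
    cell_size: float  # mm
    values: np.ndarray  # shape (nx, ny), in [0, 1]

    @property
    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys


@dataclass(frozen=True)
class HeadingHistogram:
    """Circular histogram of headings relative to the windward direction.

    0 rad means facing windward (straight upwind); this does not imply
    facing the odor source.
    """

    bin_edges: np.ndarray  # length n_bins + 1, spanning (-pi, pi]
    counts: np.ndarray
    convention: str = "0=windward"


@dataclass(frozen=True)
class Metrics:
    """Search performance summary of one trial set."""

    success_rate: float  # fraction in [0, 1]
    search_times: np.ndarray  # s, successful trials only
    spt: float  # %/s, success percentage per mean successful search time

    @property
    def n_success(self) -> int:
        return len(self.search_times)


def _cell_bounds(trials: TrialSet, cell_size: float):
    xmin, xmax, ymin, ymax = trials.plume_config.field_bounds
    nx = int(math.ceil((xmax - xmin) / cell_size))
    ny = int(math.ceil((ymax - ymin) / cell_size))
    return (xmin, ymin), nx, ny


def migration_map(trials: TrialSet, cell_size: float = 1.0) -> MigrationMap:
    """Trial-averaged binary occupancy map (default 1 mm cells).

    Each trial marks every cell its sampled positions fall in with 1
    (revisits are not double-counted); the map is the mean of those binary
    indicator maps over trials.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    if trials.n == 0:
        raise ValueError("empty trial set")
    origin, nx, ny = _cell_bounds(trials, cell_size)
    acc = np.zeros(nx * ny, dtype=np.int64)
    for tr in trials.trajectories:
        if len(tr.samples) == 0:
            raise ValueError("trajectory has no samples (recorded trials required)")
        ix = ((tr.samples["x_mm"].to_numpy() - origin[0]) / cell_size).astype(np.int64)
        iy = ((tr.samples["y_mm"].to_numpy() - origin[1]) / cell_size).astype(np.int64)
        np.clip(ix, 0, nx - 1, out=ix)
        np.clip(iy, 0, ny - 1, out=iy)
        acc[np.unique(ix * ny + iy)] += 1
    return MigrationMap(origin, cell_size, (acc / trials.n).reshape(nx, ny))


def _coarsen(values: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Block-sum ``values`` down to at most ``shape`` bins per axis."""
    nx, ny = values.shape
    bx = max(1, int(math.ceil(nx / shape[0])))
    by = max(1, int(math.ceil(ny / shape[1])))
    if bx == 1 and by == 1:
        return values
    px = (-nx) % bx
    py = (-ny) % by
    padded = np.pad(values, ((0, px), (0, py)))
    mx, my = padded.shape[0] // bx, padded.shape[1] // by
    return padded.reshape(mx, bx, my, by).sum(axis=(1, 3))


def emd(
    map_a: MigrationMap,
    map_b: MigrationMap,
    coarsen_to: tuple[int, int] | None = (30, 20),
) -> float:
    """Earth mover's distance (mm) between two migration maps.

    Both maps are normalized to unit mass and compared with the exact
    optimal-transport cost, Euclidean ground distance between cell
    centers.  ``coarsen_to`` block-sums each map to at most that many bins
    per axis first (exact transport on the raw 1 mm grid is infeasible);
    pass None to solve on the native grid.
    """
    if map_a.values.shape != map_b.values.shape or map_a.cell_size != map_b.cell_size:
        raise ValueError("maps must share grid geometry")
    if map_a.origin != map_b.origin:
        raise ValueError("maps must share grid geometry")
    a, b = map_a.values, map_b.values
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("all-zero map has no mass to transport")
    cell = map_a.cell_size
    if coarsen_to is not None:
        a = _coarsen(a, coarsen_to)
        b = _coarsen(b, coarsen_to)
        cell = cell * max(
            int(math.ceil(map_a.values.shape[0] / coarsen_to[0])),
            int(math.ceil(map_a.values.shape[1] / coarsen_to[1])),
        )
    # cell centers of the (possibly coarsened) grids
    nx, ny = a.shape
    xs = map_a.origin[0] + (np.arange(nx) + 0.5) * cell
    ys = map_a.origin[1] + (np.arange(ny) + 0.5) * cell
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])

    wa = a.ravel() / a.sum()
    wb = b.ravel() / b.sum()
    ia = np.flatnonzero(wa)
    ib = np.flatnonzero(wb)
    cost = np.linalg.norm(pts[ia][:, None, :] - pts[ib][None, :, :], axis=2)
    return _transport_lp(wa[ia], wb[ib], cost)


def _transport_lp(wa: np.ndarray, wb: np.ndarray, cost: np.ndarray) -> float:
    """Exact transportation LP: min <F, cost> s.t. row/col marginals."""
    na, nb = cost.shape
    # equality constraints: na row sums + nb column sums (drop the last,
    # redundant, row to keep the system full rank)
    rows, cols, data = [], [], []
    for i in range(na):
        rows.extend([i] * nb)
        cols.extend(range(i * nb, (i + 1) * nb))
        data.extend([1.0] * nb)
    for j in range(nb - 1):
        rows.extend([na + j] * na)
        cols.extend(range(j, na * nb, nb))
        data.extend([1.0] * na)
    a_eq = coo_matrix((data, (rows, cols)), shape=(na + nb - 1, na * nb))
    b_eq = np.concatenate([wa, wb[:-1]])
    res = linprog(cost.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - LP on a feasible polytope
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def heading_histogram(
    trials: TrialSet,
    n_bins: int = 36,
    wind_direction: tuple[float, float] | None = None,
) -> HeadingHistogram:
    """Histogram of per-sample headings relative to the windward direction.

    Every sample of every trial counts once; 0 is the upwind (windward)
    bearing.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    wd = wind_direction if wind_direction is not None else trials.plume_config.wind_direction
    upwind = math.atan2(-wd[1], -wd[0])
    edges = np.linspace(-math.pi, math.pi, n_bins + 1)
    counts = np.zeros(n_bins, dtype=np.int64)
    for tr in trials.trajectories:
        h = tr.samples["heading_rad"].to_numpy()
        rel = np.mod(h - upwind + math.pi, 2.0 * math.pi) - math.pi
        counts += np.histogram(rel, bins=edges)[0]
    return HeadingHistogram(edges, counts)


def metrics(trials: TrialSet, time_limit: float | None = None) -> Metrics:
    """Success rate, successful search times, and success rate per unit time.

    SPT = (success rate in percent) / (mean successful search time in s);
    0 when there are no successes.
    """
    rate = trials.success_count / trials.n if trials.n else 0.0
    times = trials.search_times
    spt = (rate * 100.0) / times.mean() if len(times) else 0.0
    return Metrics(rate, times, spt)


class PiecewiseFit(NamedTuple):
    a_low: float
    b_low: float
    a_high: float
    b_high: float
    breakpoint: float
    sse: float


def fit_piecewise_gain(
    f_bins: Sequence[float],
    mean_speeds: Sequence[float],
    breakpoint_candidates: Sequence[float],
) -> PiecewiseFit:
    """Two-segment least-squares line fit over candidate breakpoints.

    For each candidate the bins with f <= candidate and f > candidate are
    fitted by separate least-squares lines (each side needs >= 3 bins);
    the fit minimizing the total squared error is returned.
    """
    f = np.asarray(f_bins, dtype=float)
    y = np.asarray(mean_speeds, dtype=float)
    if f.shape != y.shape or f.ndim != 1:
        raise ValueError("f_bins and mean_speeds must be equal-length 1D")
    best: PiecewiseFit | None = None
    for bp in breakpoint_candidates:
        lo = f <= bp
        hi = ~lo
        if lo.sum() < 3 or hi.sum() < 3:
            raise ValueError(
                f"breakpoint candidate {bp} leaves fewer than 3 bins on one side"
            )
        (a1, b1), r1 = _line_fit(f[lo], y[lo])
        (a2, b2), r2 = _line_fit(f[hi], y[hi])
        fit = PiecewiseFit(a1, b1, a2, b2, float(bp), r1 + r2)
        if best is None or fit.sse < best.sse:
            best = fit
    return best


def _line_fit(x: np.ndarray, y: np.ndarray):
    design = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return (float(coef[0]), float(coef[1])), float(resid @ resid)


def recover_speed_gain(
    trials: TrialSet,
    bin_width: float = 0.1,
    f_range: tuple[float, float] = (0.0, 1.2),
    breakpoint_candidates: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    matched_only: bool = True,
    min_count: int = 3,
):
    """Recover the translational gain K_v(f) from logged trajectories.

    At each detection onset the commanded speed equals K_v(f) exactly (the
    surge envelope is 1 there), so onset samples expose the gain table:
    onset speeds are binned by the frequency the controller measured
    (the logged f) and the bin means fitted with
    :func:`fit_piecewise_gain`.

    The counter quantizes f to multiples of 1/window, so run the recovery
    batch with a 10 s frequency window to resolve 0.1 Hz bins (three
    populated bins are needed on each side of every candidate breakpoint).

    Returns ``(fit, f_centers, mean_speeds)``.
    """
    f_samples: list[np.ndarray] = []
    v_samples: list[np.ndarray] = []
    for tr in trials.trajectories:
        df = tr.samples
        hit = (df["left_hit"] | df["right_hit"]).to_numpy()
        onset = hit & ~np.concatenate([[False], hit[:-1]])
        if matched_only:
            onset &= df["matched"].to_numpy()
        f_samples.append(df["f_hz"].to_numpy()[onset])
        v_samples.append(df["v_mms"].to_numpy()[onset])
    f_arr = np.concatenate(f_samples)
    v_arr = np.concatenate(v_samples)
    # bins centered on multiples of bin_width, so the counter's quantized
    # frequencies fall mid-bin rather than on edges
    edges = np.arange(f_range[0] - bin_width / 2, f_range[1] + bin_width, bin_width)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (f_arr >= lo) & (f_arr < hi)
        if sel.sum() >= min_count:
            centers.append((lo + hi) / 2.0)
            means.append(v_arr[sel].mean())
    centers_arr = np.asarray(centers)
    feasible = [
        bp
        for bp in breakpoint_candidates
        if (centers_arr <= bp).sum() >= 3 and (centers_arr > bp).sum() >= 3
    ]
    if not feasible:
        raise ValueError("no breakpoint candidate has 3 populated bins per side")
    fit = fit_piecewise_gain(centers, means, feasible)
    return fit, centers_arr, np.asarray(means)
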