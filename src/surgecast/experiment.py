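"""Experiment orchestration: run controller x scenario batches, write
trajectories, metrics, maps and figures, and record a manifest that fully
determines re-execution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import __version__
from .simulator import TrialSet, run_trial
from .analysis import heading_histogram, metrics, migration_map
from .config import ExperimentConfig, _to_plain
from .controllers import make_controller
from dataclasses import replace

__all__ = ["RunManifest", "run_experiment", "write_migration_map", "read_migration_map"]

log = logging.getLogger("surgecast")


@dataclass
class RunManifest:
    config: dict
    version: str
    started: str
    finished: str
    trials: list  # per-trial records: batch, seed, outcome, search_time

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def write_migration_map(m, path) -> None:
    """Dense matrix text format with a one-line geometry header."""
    header = (
        f"origin_x_mm={m.origin[0]} origin_y_mm={m.origin[1]} "
        f"cell_size_mm={m.cell_size} nx={m.values.shape[0]} ny={m.values.shape[1]}"
    )
    np.savetxt(path, m.values, header=header)


def read_migration_map(path):
    from .analysis import MigrationMap

    with open(path) as fh:
        header = fh.readline().lstrip("# ").split()
    kv = dict(item.split("=") for item in header)
    values = np.loadtxt(path)
    values = values.reshape(int(kv["nx"]), int(kv["ny"]))
    return MigrationMap(
        (float(kv["origin_x_mm"]), float(kv["origin_y_mm"])),
        float(kv["cell_size_mm"]),
        values,
    )


def run_experiment(config: ExperimentConfig, outdir, progress_every: int = 50) -> RunManifest:
    """Execute every controller x scenario batch and write all artifacts.

    Layout under ``outdir``: ``trajectories/<scenario>/<controller>/trial_<seed>.csv``,
    ``metrics.json``, ``maps/<scenario>_<controller>.txt``, ``figures/...``,
    ``manifest.json`` and ``run.log``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    cfg_plain = _to_plain(config)
    log.info("experiment start: %d controllers x %d scenarios x n=%d",
             len(config.controllers), len(config.batch.scenarios), config.batch.n)

    all_metrics: dict = {}
    trial_records: list = []
    trial_sets: dict[tuple[str, str], TrialSet] = {}
    try:
        for scenario, starts in config.batch.scenarios.items():
            for name in config.controllers:
                controller = make_controller(name, config.controller_params_for(name))
                trajdir = outdir / "trajectories" / scenario / name
                trajdir.mkdir(parents=True, exist_ok=True)
                trajectories = []
                for i in range(config.batch.n):
                    seed = config.batch.base_seed + i
                    tcfg = replace(
                        config.trial,
                        seed=seed,
                        start_position=tuple(starts[i % len(starts)]),
                    )
                    try:
                        tr = run_trial(config.plume, controller, tcfg)
                    except Exception as exc:  # keep going; record the failure
                        log.exception("trial failed: %s/%s seed=%d", scenario, name, seed)
                        trial_records.append(
                            dict(batch=f"{scenario}/{name}", seed=seed,
                                 outcome="error", search_time=None, error=str(exc))
                        )
                        continue
                    trajectories.append(tr)
                    trial_records.append(
                        dict(batch=f"{scenario}/{name}", seed=seed,
                             outcome=tr.outcome, search_time=tr.search_time)
                    )
                    if config.trial.record:
                        tr.to_csv(trajdir / f"trial_{seed}.csv")
                    if (i + 1) % progress_every == 0:
                        log.info("%s/%s: %d/%d trials", scenario, name, i + 1, config.batch.n)
                ts = TrialSet(trajectories, config.plume, config.trial)
                trial_sets[(scenario, name)] = ts
                m = metrics(ts)
                all_metrics[f"{scenario}/{name}"] = dict(
                    n=ts.n,
                    success_count=ts.success_count,
                    success_rate=m.success_rate,
                    mean_search_time=float(m.search_times.mean()) if m.n_success else None,
                    median_search_time=float(np.median(m.search_times)) if m.n_success else None,
                    spt=m.spt,
                )
                log.info("%s/%s done: %s", scenario, name, all_metrics[f"{scenario}/{name}"])

        (outdir / "metrics.json").write_text(json.dumps(all_metrics, indent=1))
        if config.trial.record:
            _write_maps_and_figures(config, outdir, trial_sets)
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = RunManifest(
        config=cfg_plain,
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        trials=trial_records,
    )
    manifest.save(outdir / "manifest.json")
    return manifest


def _write_maps_and_figures(config, outdir: Path, trial_sets) -> None:
    mapdir = outdir / "maps"
    figdir = outdir / "figures"
    mapdir.mkdir(exist_ok=True)
    figdir.mkdir(exist_ok=True)
    for (scenario, name), ts in trial_sets.items():
        if ts.n == 0:
            continue
        m = migration_map(ts, config.analysis.migration_cell_size)
        write_migration_map(m, mapdir / f"{scenario}_{name}.txt")
        plot_migration_map(m, figdir / f"map_{scenario}_{name}.png",
                           title=f"{name} ({scenario})")
        plot_trajectories(ts, figdir / f"trajectories_{scenario}_{name}.png",
                          title=f"{name} ({scenario})")
        hh = heading_histogram(ts, config.analysis.heading_bins)
        plot_heading_histogram(hh, figdir / f"headings_{scenario}_{name}.png",
                               title=f"{name} ({scenario})")
    plot_metric_bars(trial_sets, figdir / "comparison.png")


def plot_trajectories(ts: TrialSet, path, max_trials: int = 100, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for tr in ts.trajectories[:max_trials]:
        color = "tab:blue" if tr.success else "0.3"
        ax.plot(tr.samples["x_mm"], tr.samples["y_mm"], color=color, lw=0.4, alpha=0.5)
    ax.plot(*ts.plume_config.source_position, "r*", ms=12)
    xmin, xmax, ymin, ymax = ts.plume_config.field_bounds
    ax.set(xlim=(xmin, xmax), ylim=(ymin, ymax), xlabel="x (mm)", ylabel="y (mm)",
           title=title, aspect="equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_migration_map(m, path, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    xs, ys = m.cell_centers
    im = ax.imshow(
        m.values.T, origin="lower", extent=(xs[0], xs[-1], ys[0], ys[-1]),
        aspect="equal", cmap="viridis", vmin=0.0,
    )
    fig.colorbar(im, ax=ax, label="pass probability")
    ax.set(xlabel="x (mm)", ylabel="y (mm)", title=title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_heading_histogram(hh, path, title: str = "") -> None:
    fig, ax = plt.subplots(subplot_kw=dict(projection="polar"), figsize=(4.5, 4.5))
    centers = (hh.bin_edges[:-1] + hh.bin_edges[1:]) / 2.0
    width = hh.bin_edges[1] - hh.bin_edges[0]
    ax.bar(centers, hh.counts, width=width, bottom=0.0, alpha=0.8)
    ax.set_theta_zero_location("N")
    ax.set_title(f"{title} (0 = windward)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_metric_bars(trial_sets, path) -> None:
    scenarios = sorted({k[0] for k in trial_sets})
    names = sorted({k[1] for k in trial_sets})
    fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
    width = 0.8 / max(1, len(scenarios))
    xs = np.arange(len(names))
    for si, scen in enumerate(scenarios):
        ms = [metrics(trial_sets[(scen, n)]) for n in names]
        axes[0].bar(xs + si * width, [m.success_rate * 100 for m in ms], width, label=scen)
        axes[1].bar(
            xs + si * width,
            [m.search_times.mean() if m.n_success else 0.0 for m in ms],
            width,
        )
        axes[2].bar(xs + si * width, [m.spt for m in ms], width)
    for ax, label in zip(axes, ["success rate (%)", "mean search time (s)", "SPT (%/s)"]):
        ax.set_xticks(xs + width * (len(scenarios) - 1) / 2)
        ax.set_xticklabels(names, rotation=20)
        ax.set_ylabel(label)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
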