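"""Experiment configuration: a single YAML file drives the full comparison.

Every parameter has a package default, so an empty file (or no file) is a
valid configuration; unknown keys are rejected with their key path to
catch typos.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .controllers import CastingParams, MiM2Params, SurgeZigzagParams
from .plume import PlumeConfig
from .sensing import AntennaGeometry
from .simulator import TrialConfig

__all__ = ["ExperimentConfig", "BatchConfig", "AnalysisConfig", "load_config", "save_config"]

CONTROLLER_NAMES = ("mim2", "surge_zigzag", "casting")


@dataclass(frozen=True)
class BatchConfig:
    n: int = 100  # trials per controller per scenario
    base_seed: int = 0
    scenarios: dict = field(
        default_factory=lambda: {
            "center": [(300.0, 0.0)],
            "offset": [(300.0, 100.0), (300.0, -100.0)],
        }
    )

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("batch.n must be >= 1")


@dataclass(frozen=True)
class AnalysisConfig:
    migration_cell_size: float = 1.0  # mm
    heading_bins: int = 36
    emd_coarsen: tuple[int, int] = (30, 20)


@dataclass(frozen=True)
class ExperimentConfig:
    plume: PlumeConfig = field(default_factory=PlumeConfig)
    controllers: tuple[str, ...] = CONTROLLER_NAMES
    controller_params: dict = field(default_factory=dict)
    trial: TrialConfig = field(default_factory=TrialConfig)
    batch: BatchConfig = field(default_factory=BatchConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        for name in self.controllers:
            if name not in CONTROLLER_NAMES:
                raise ValueError(
                    f"unknown controller {name!r}; expected one of {CONTROLLER_NAMES}"
                )

    def controller_params_for(self, name: str):
        cls = {
            "mim2": MiM2Params,
            "surge_zigzag": SurgeZigzagParams,
            "casting": CastingParams,
        }[name]
        overrides = self.controller_params.get(name, {})
        return _build(cls, overrides, f"controller_params.{name}") if overrides else cls()


def _build(cls, data: dict, path: str):
    """Construct a (nested) dataclass from a dict, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            raise ValueError(f"unknown configuration key: {path}.{key}")
        ftype = fields[key].type
        sub = _SUBSECTIONS.get((cls, key))
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, f"{path}.{key}")
        elif key in _TUPLE_KEYS and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(
                tuple(v) if isinstance(v, (list, tuple)) else v for v in value
            )
        else:
            kwargs[key] = value
    return cls(**kwargs)


_SUBSECTIONS = {
    (ExperimentConfig, "plume"): PlumeConfig,
    (ExperimentConfig, "trial"): TrialConfig,
    (ExperimentConfig, "batch"): BatchConfig,
    (ExperimentConfig, "analysis"): AnalysisConfig,
    (TrialConfig, "antenna"): AntennaGeometry,
}

_TUPLE_KEYS = {
    "source_position",
    "wind_direction",
    "field_bounds",
    "start_position",
    "controllers",
    "emd_coarsen",
    "vision_gains",
}


def load_config(path: str | Path | None = None) -> ExperimentConfig:
    """Load a YAML experiment configuration; missing keys take defaults.

    ``None`` or an empty file yields the full default configuration
    (MiM2 + both baselines, start (300, 0), 300 s limit, 10 mm radius).
    """
    if path is None:
        return ExperimentConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)
    if data is None:
        return ExperimentConfig()
    if not isinstance(data, dict):
        raise ValueError("configuration root must be a mapping")
    if "scenarios" in data.get("batch", {}):
        scen = data["batch"]["scenarios"]
        data["batch"]["scenarios"] = {
            k: [tuple(p) for p in v] for k, v in scen.items()
        }
    return _build(ExperimentConfig, data, "config")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return str(obj)
    return obj


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    """Write the configuration as YAML (round-trips through load_config)."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
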