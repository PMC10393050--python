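"""Run configuration: a single YAML file driving simulate/analyze runs.

All relative paths in a config are resolved against the config file's
directory so a fixture directory can be moved as a unit. Unknown keys and
invalid values raise :class:`ConfigError` naming the offending field path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError
from .models import TrainConfig
from .reference import reference_levels
from .simulator import MotionModel, SimulationProtocol

__all__ = ["RunConfig", "load_config"]


def _build(cls, block: dict | None, path: str):
    block = dict(block or {})
    allowed = {f.name for f in dc_fields(cls)}
    for key in block:
        if key not in allowed:
            raise ConfigError(f"{path}.{key}: unknown field")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass
class LockInConfig:
    bandwidth_bins: int = 1
    target_length: int = 500


@dataclass
class ModelConfig:
    backend: str = "svm"
    opt_budget: int = 15
    train: TrainConfig = field(default_factory=TrainConfig)


@dataclass
class DatasetConfig:
    videos_per_level: int = 5
    levels: list[float] | None = None  # default: packaged reference table
    out_dir: str = "videos"


@dataclass
class RunConfig:
    """Resolved configuration of one run."""

    seed: int
    protocol: SimulationProtocol
    motion: MotionModel
    lockin: LockInConfig
    model: ModelConfig
    dataset: DatasetConfig
    base_dir: Path
    out_dir: Path

    @property
    def levels(self) -> list[float]:
        if self.dataset.levels is not None:
            return [float(v) for v in self.dataset.levels]
        return list(reference_levels())

    @property
    def video_dir(self) -> Path:
        return self.base_dir / self.dataset.out_dir

    @property
    def manifest_path(self) -> Path:
        return self.video_dir / "manifest.csv"


def load_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    try:
        raw: dict[str, Any] = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML ({exc})") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    known = {"seed", "protocol", "motion", "lockin", "model", "dataset", "paths"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"{key}: unknown top-level field")

    if seed_override is not None:
        seed = int(seed_override)
    elif "seed" in raw:
        seed = int(raw["seed"])
    else:
        raise ConfigError("seed: required field is missing")

    protocol_block = dict(raw.get("protocol") or {})
    protocol_block.setdefault("seed", seed)
    protocol = _build(SimulationProtocol, protocol_block, "protocol")
    motion = _build(MotionModel, raw.get("motion"), "motion")
    lockin = _build(LockInConfig, raw.get("lockin"), "lockin")

    model_block = dict(raw.get("model") or {})
    train_block = model_block.pop("train", None)
    model = _build(ModelConfig, model_block, "model")
    if train_block is not None:
        model.train = _build(TrainConfig, train_block, "model.train")
    if model.backend not in ("svm", "cnn_lstm"):
        raise ConfigError(f"model.backend: must be 'svm' or 'cnn_lstm'")

    dataset = _build(DatasetConfig, raw.get("dataset"), "dataset")

    paths = dict(raw.get("paths") or {})
    base_dir = path.parent.resolve()
    out_dir = base_dir / str(paths.get("out_dir", "runs"))

    return RunConfig(
        seed=seed,
        protocol=protocol,
        motion=motion,
        lockin=lockin,
        model=model,
        dataset=dataset,
        base_dir=base_dir,
        out_dir=out_dir,
    )
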