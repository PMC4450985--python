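"""JSON run configuration with strict key checking."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .detect import DetectionConfig
from .simulate import BackgroundParams, SimulationConfig
from .stacks import ValidationError

__all__ = ["RunConfig", "load_run_config", "simulation_config_from_dict"]

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run; echoed into outputs."""

    schema_version: int = CONFIG_SCHEMA_VERSION
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    n_trees: int = 500
    mtry: int | None = None
    min_leaf: int = 5
    level: float = 0.95
    n_reps: int = 1000
    seed: int = 0

    def validate(self) -> None:
        self.detection.validate()
        if self.n_trees < 1 or self.min_leaf < 1:
            raise ValidationError("n_trees and min_leaf must be >= 1")
        if not (0 < self.level < 1):
            raise ValidationError("level must be in (0, 1)")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


def _from_dict(cls, doc: dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - names
    if unknown:
        raise ValidationError(f"unknown keys in {where}: {sorted(unknown)}")
    return cls(**doc)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict):
        raise ValidationError("run config must be a JSON object")
    version = doc.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValidationError(f"unsupported config schema_version {version}")
    det = doc.pop("detection", {})
    cfg = _from_dict(RunConfig, doc, "run config")
    cfg.detection = _from_dict(DetectionConfig, det, "detection config")
    cfg.schema_version = version
    cfg.validate()
    return cfg


def simulation_config_from_dict(doc: dict) -> SimulationConfig:
    doc = dict(doc)
    bg = doc.pop("background_params", {})
    cfg = _from_dict(SimulationConfig, doc, "simulation config")
    if isinstance(bg, dict):
        cfg.background_params = _from_dict(BackgroundParams, bg, "background_params")
    if isinstance(cfg.shape, list):
        cfg.shape = tuple(cfg.shape)
    cfg.validate()
    return cfg
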