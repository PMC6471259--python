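"""Nested pipeline configuration, loadable from a single YAML file.

Unknown keys are rejected so typos fail loudly.  Defaults match the
documented module defaults (5 % segmentation threshold, T = 60 resample
points, M = 6 windows, 32 LSTM hidden units, 500 epochs, 30 % hold-out).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import ClassifierConfig
from .inertial import WindowingConfig
from .segmentation import SegmentationConfig
from .synthetic import GeneratorConfig
from .types import ValidationError

__all__ = ["EvalConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class EvalConfig:
    test_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.test_fraction < 1:
            raise ValidationError("test_fraction must be in (0, 1)")


@dataclass(frozen=True)
class FeaturesConfig:
    unit_basis: bool = True
    n_points: int = 60
    M: int = 6


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    model: ClassifierConfig = field(default_factory=ClassifierConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @property
    def windowing(self) -> WindowingConfig:
        return WindowingConfig(M=self.features.M)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown config keys under '{path}': {sorted(unknown)}")
    return cls(**data)


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from YAML; missing blocks keep their defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config root must be a mapping")
    blocks = {
        "segmentation": SegmentationConfig,
        "features": FeaturesConfig,
        "model": ClassifierConfig,
        "eval": EvalConfig,
        "generator": GeneratorConfig,
    }
    unknown = set(raw) - set(blocks)
    if unknown:
        raise ValidationError(f"{path}: unknown top-level config keys {sorted(unknown)}")
    kwargs = {}
    for name, cls in blocks.items():
        if name in raw:
            data = dict(raw[name] or {})
            if name == "generator":
                data = _coerce_generator(data)
            kwargs[name] = _build(cls, data, name)
    return PipelineConfig(**kwargs)


def _coerce_generator(data: dict) -> dict:
    """YAML-friendly spellings for the generator's enum-keyed fields."""
    from .classify import ModalityId
    from .types import BehaviorLabel

    if "behaviors" in data:
        data["behaviors"] = tuple(BehaviorLabel[b] for b in data["behaviors"])
    if "noise_sd_per_modality" in data:
        data["noise_sd_per_modality"] = {
            ModalityId[k]: float(v) for k, v in data["noise_sd_per_modality"].items()
        }
    for key in ("height_range_m", "active_window_s"):
        if key in data:
            data[key] = tuple(data[key])
    return data
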