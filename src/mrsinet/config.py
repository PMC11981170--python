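"""Experiment configuration: YAML round-trip with strict key validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .classifier_net import ClassifierConfig
from .errors import ConfigurationError
from .saliency import DEFAULT_REGIONS
from .transform_net import TransformNetConfig


@dataclass
class SimulatorSection:
    """Simulation stage settings; augmentation defaults follow the
    standard table (phase +-pi/4, broadening 0-40 Hz, noise SD 0.05-1)."""

    n: int = 2000
    n_per_class: int = 500
    master_seed: int = 0
    split_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    field_range: Tuple[float, float] = (3.0, 7.0)
    discrete_fields: bool = False
    phase_range: Tuple[float, float] = (-float(np.pi) / 4, float(np.pi) / 4)
    broadening_range: Tuple[float, float] = (0.0, 40.0)
    noise_range: Tuple[float, float] = (0.05, 1.0)
    water_amplitude: float = 0.0
    intensity_scale: Optional[float] = None  # None -> calibrated default
    phantom: bool = False

    def augment_params(self):
        from .simulate import AugmentParams, INTENSITY_SCALE_DEFAULT
        return AugmentParams(
            phase_range=tuple(self.phase_range),
            broadening_range=tuple(self.broadening_range),
            noise_range=tuple(self.noise_range),
            water_amplitude=self.water_amplitude,
            intensity_scale=(self.intensity_scale
                             if self.intensity_scale is not None
                             else INTENSITY_SCALE_DEFAULT))


@dataclass
class EvaluationSection:
    threshold: float = 0.5
    windows: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS))
    n_saliency_maps: int = 25


@dataclass
class TrainingSeeds:
    transform: int = 0
    classifier: int = 0


@dataclass
class ExperimentConfig:
    simulator: SimulatorSection = field(default_factory=SimulatorSection)
    transform: TransformNetConfig = field(default_factory=TransformNetConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    seeds: TrainingSeeds = field(default_factory=TrainingSeeds)
    out_dir: str = "mrsinet_run"

    def section_dict(self, name: str) -> Dict:
        return _to_plain(getattr(self, name))

    def to_dict(self) -> Dict:
        out = {name: _to_plain(getattr(self, name))
               for name in ("simulator", "transform", "classifier",
                            "evaluation", "seeds")}
        out["out_dir"] = self.out_dir
        return out

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _build_section(cls, data: Dict, where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section '{where}'")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        if isinstance(val, list):
            val = tuple(val) if f.name != "windows" else val
        if f.name == "windows" and isinstance(val, dict):
            val = {k: tuple(v) for k, v in val.items()}
        kwargs[f.name] = val
    return cls(**kwargs)


_SECTIONS = {
    "simulator": SimulatorSection,
    "transform": TransformNetConfig,
    "classifier": ClassifierConfig,
    "evaluation": EvaluationSection,
    "seeds": TrainingSeeds,
}


def config_from_dict(data: Optional[Dict]) -> ExperimentConfig:
    """Build a validated ExperimentConfig; unknown keys are rejected."""
    data = dict(data or {})
    out_dir = data.pop("out_dir", "mrsinet_run")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
    sections = {name: _build_section(cls, data.get(name, {}) or {}, name)
                for name, cls in _SECTIONS.items()}
    return ExperimentConfig(out_dir=out_dir, **sections)


def load_config(path: Optional[str]) -> ExperimentConfig:
    """Load a YAML experiment configuration (None -> all defaults)."""
    if path is None:
        return ExperimentConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    return config_from_dict(data)
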