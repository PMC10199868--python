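"""Structured pipeline configuration with strict YAML (de)serialisation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import BlendSpec
from .core import PSFModel
from .cyclegan import GANConfig
from .iy import IYConfig
from .phantom import PhantomSpec

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class EvaluationConfig:
    radiomics_bins: int = 64
    ttest_alpha: float = 0.05
    ttest_correction: str = "bonferroni"
    joint_hist_bins: int = 64


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one end-to-end experiment needs, in nested sections.

    The desk-scale default: 12-region 64^3 phantoms, 8 real + blended
    samples to 12 per profile, a tiny translator, one train/test split.
    """

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    iy: IYConfig = field(default_factory=IYConfig)
    blend: BlendSpec = field(default_factory=BlendSpec)
    gan: GANConfig = field(default_factory=GANConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    n_samples: int = 8
    n_augmented_target: int = 12
    n_test: int = 2
    master_seed: int = 0
    output_dir: str = "pvcbrain_run"


_SECTION_TYPES = {
    "phantom": PhantomSpec,
    "iy": IYConfig,
    "blend": BlendSpec,
    "gan": GANConfig,
    "evaluation": EvaluationConfig,
}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def _build(cls, data: dict, context: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        ftype = names[key].type
        if key == "psf" and isinstance(value, dict):
            value = _build(PSFModel, value, f"{context}.psf")
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    return _to_plain(config)


def config_from_dict(data: dict) -> PipelineConfig:
    names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValueError(f"section {key!r} must be a mapping")
            kwargs[key] = _build(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return config_from_dict(data)
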