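"""Run configuration: one YAML file covering every stage of the pipeline.

The shipped defaults equal the tuned operating point of the pipeline:
STFT kernel size 50, hop 1, 12 Mel filters, 400 Hz working rate, patch
size 200 (8 patches per 1,600-sample window).  Unknown keys are rejected
so that typos fail loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .labeling import LabelScheme
from .model import ModelConfig
from .spectral import SpectralConfig
from .synthetic import SyntheticSpec
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs: nested stage configs plus seed and windowing."""

    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    labels: LabelScheme = field(default_factory=LabelScheme)
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    window_len: int = 1600
    patch_len: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.window_len % self.patch_len != 0:
            raise ConfigError(
                f"window_len {self.window_len} must be divisible by patch_len {self.patch_len}")


_SECTIONS = {
    "spectral": SpectralConfig,
    "model": ModelConfig,
    "train": TrainConfig,
    "labels": LabelScheme,
    "synthetic": SyntheticSpec,
}
_TUPLE_FIELDS = {"conv_widths", "thresholds", "class_names", "state_sequence"}


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"valid keys: {sorted(names)}")
    clean = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(tuple(item) if isinstance(item, list) else item for item in v)
        elif k == "perclos_by_state" and isinstance(v, dict):
            v = {state: tuple(pair) for state, pair in v.items()}
        clean[k] = v
    return cls(**clean)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    top_keys = set(_SECTIONS) | {"window_len", "patch_len", "seed"}
    unknown = set(raw) - top_keys
    if unknown:
        raise ConfigError(
            f"unknown top-level key(s) {sorted(unknown)}; valid keys: {sorted(top_keys)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            if not isinstance(raw[section], dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            kwargs[section] = _build_section(cls, raw[section], section)
    for key in ("window_len", "patch_len", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg: RunConfig, path) -> Path:
    """Persist the fully resolved configuration next to run outputs."""
    raw = _to_plain(dataclasses.asdict(cfg))
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
    return path
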