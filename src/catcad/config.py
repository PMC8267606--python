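"""Structured run configuration with strict (unknown keys rejected) loading."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from catcad.bifactor import EstimationOptions
from catcad.cad import CadConfig
from catcad.cat import CatConfig, ScoreTransform


@dataclass(frozen=True)
class SynthConfig:
    n_items: int = 211
    n_persons: int = 713
    n_poor_items: int = 0
    prevalence: float = 0.284
    signal_strength: float = 2.0


@dataclass(frozen=True)
class ValidationConfig:
    folds: int = 10
    t1_min_sensitivity: float = 0.95
    t3_min_specificity: float = 0.93


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration for CLI runs; every section is optional in
    the YAML file and falls back to the documented defaults."""

    seed: int = 0
    estimation: EstimationOptions = field(default_factory=EstimationOptions)
    cat: CatConfig = field(default_factory=CatConfig)
    transform: ScoreTransform = field(default_factory=ScoreTransform)
    cad: CadConfig = field(default_factory=CadConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    validation: ValidationConfig = field(default_factory=ValidationConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _build(cls, data: dict[str, Any], where: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {where!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown config key(s) in {where!r}: {sorted(unknown)}; "
            f"allowed: {sorted(known)}"
        )
    return cls(**data)


_SECTIONS = {
    "estimation": EstimationOptions,
    "cat": CatConfig,
    "transform": ScoreTransform,
    "cad": CadConfig,
    "synth": SynthConfig,
    "validation": ValidationConfig,
}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys anywhere."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path}: top level must be a mapping")
    unknown = set(raw) - (set(_SECTIONS) | {"seed"})
    if unknown:
        raise ValueError(f"config file {path}: unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name], name)
    return RunConfig(**kwargs)
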