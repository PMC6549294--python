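"""Run configuration: one structured file drives all pipeline stages.

Every "user-defined" threshold of the pipeline has an explicit key and
default here. Unknown keys in a config file are errors (catching typos in
threshold names), and the resolved config is serialised into every output
directory for provenance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calcium import CalciumConfig
from .morpho import MorphoConfig
from .synth import CalciumParams, FieldParams, MaturationModel

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class SimulateConfig:
    """Synthetic-plate generation settings."""

    n_wells_per_div: int = 2
    n_fields_per_well: int = 2
    n_recordings_per_div: int = 2
    plate: str = "P1"
    cell_type: str = "cortical"
    condition: str = "control"
    experiment: str = "E1"
    replicate: int = 1


@dataclass
class ScoreConfig:
    """Score-model and classifier settings."""

    intercorrelation_cutoff: float = 0.75
    exclude_intensity: bool = True
    control_condition: str = "control"
    classifier_method: str = "random_forest"
    n_estimators_grid: tuple[int, ...] = (100, 250, 500, 1000)
    max_features_grid: tuple = ("sqrt", 0.3, 0.6)
    cv_folds: int = 10
    test_size: float = 1 / 3
    seed: int = 0


@dataclass
class RunConfig:
    """Top-level configuration for simulate / profile / score runs."""

    field: FieldParams = dataclasses.field(default_factory=FieldParams)
    maturation: MaturationModel = dataclasses.field(default_factory=MaturationModel)
    calcium_truth: CalciumParams = dataclasses.field(default_factory=CalciumParams)
    simulate: SimulateConfig = dataclasses.field(default_factory=SimulateConfig)
    morpho: MorphoConfig = dataclasses.field(default_factory=MorphoConfig)
    calcium: CalciumConfig = dataclasses.field(default_factory=CalciumConfig)
    score: ScoreConfig = dataclasses.field(default_factory=ScoreConfig)
    seed: int = 0


_SECTIONS = {
    "field": FieldParams,
    "maturation": MaturationModel,
    "calcium_truth": CalciumParams,
    "simulate": SimulateConfig,
    "morpho": MorphoConfig,
    "calcium": CalciumConfig,
    "score": ScoreConfig,
}

_TUPLE_FIELDS = {
    "shape", "frangi_scales", "div_levels", "neuronal_radius", "glial_radius",
    "dendrite_scale_range", "soma_radius", "n_estimators_grid",
    "max_features_grid",
}


def _build(cls, data: dict, path: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config key(s) under {path!r}: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; missing sections take defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {
        name: _build(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(seed=int(raw.get("seed", 0)), **kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Serialise the resolved configuration to YAML (run provenance)."""
    def _plain(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [_plain(v) for v in obj]
        return obj

    Path(path).write_text(yaml.safe_dump(_plain(config), sort_keys=False))
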