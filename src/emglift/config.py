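"""Run configuration: one YAML-backed object covering every tunable.

Unknown keys are rejected by name, and a config round-trips through its
file representation bit-exactly (YAML scalar round-tripping of Python
floats is exact via ``repr``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import WindowGrid
from .mlr import MLROptions
from .preprocessing import FilterSpec
from .synthetic import SimConfig
from .evaluation import PipelineConfig

__all__ = ["RunConfig"]


def _from_dict(cls, data: dict, context: str):
    """Strict dataclass construction: unknown keys raise by name."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {context}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _from_dict(f.type, v, f"{context}.{f.name}")
        kwargs[f.name] = v
    return cls(**kwargs)


def _tuplify(obj):
    if isinstance(obj, list):
        return tuple(_tuplify(v) for v in obj)
    if isinstance(obj, dict):
        return {k: _tuplify(v) for k, v in obj.items()}
    return obj


@dataclass(frozen=True)
class RunConfig:
    """Aggregate of simulator, preprocessing, grid, selection and model options."""

    sim: SimConfig = field(default_factory=SimConfig)
    grid: WindowGrid = field(default_factory=WindowGrid)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    _SECTIONS = {
        "sim": SimConfig,
        "grid": WindowGrid,
        "pipeline": PipelineConfig,
    }
    _NESTED = {
        "pipeline": {"filter_spec": FilterSpec, "mlr_options": MLROptions},
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - set(cls._SECTIONS)
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        parts = {}
        for section, section_cls in cls._SECTIONS.items():
            sec = {k: _tuplify(v) for k, v in dict(data.get(section, {})).items()}
            for key, sub_cls in cls._NESTED.get(section, {}).items():
                if key in sec and isinstance(sec[key], dict):
                    sec[key] = _from_dict(sub_cls, sec[key], f"{section}.{key}")
            parts[section] = _from_dict(section_cls, sec, section)
        return cls(**parts)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        )


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    return obj
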