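"""Pipeline configuration: one YAML file, per-stage sections, strict keys."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .preprocess import PreprocessParams
from .synthetic_colony import GrowthSpec, TextureSpec, texture_preset
from .texture_features import LBPParams

__all__ = ["ConfigError", "SimulateConfig", "PipelineConfig"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


def _from_mapping(cls, data: dict[str, Any], where: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}; allowed {sorted(names)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}") from exc


@dataclass(frozen=True)
class SimulateConfig:
    """Synthetic-ensemble section: texture classes and shared growth."""

    classes: tuple = ()
    growth: GrowthSpec = field(default_factory=GrowthSpec)
    image_size: int = 256
    folder: str = "synthetic-Cam1"
    rotate_frames: bool = False
    plate_edge: bool = False

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "SimulateConfig":
        data = dict(data)
        raw_classes = data.pop("classes", [])
        classes = []
        for i, entry in enumerate(raw_classes):
            entry = dict(entry)
            count = int(entry.pop("count", 1))
            name = entry.pop("class_name", None)
            if name is None:
                raise ConfigError(f"simulate.classes[{i}]: class_name is required")
            spec = texture_preset(name) if not entry else _from_mapping(
                TextureSpec, {"class_name": name, **entry}, f"simulate.classes[{i}]"
            )
            classes.append((spec, count))
        growth = data.pop("growth", {})
        cfg = _from_mapping(cls, {**data, "classes": tuple(classes)}, "simulate")
        return dataclasses.replace(
            cfg, growth=_from_mapping(GrowthSpec, growth, "simulate.growth")
        )


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the pipeline plus paths and the master seed."""

    master_seed: int = 0
    input_dir: str | None = None
    simulate: SimulateConfig | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    lbp: LBPParams = field(default_factory=LBPParams)
    n_modes: int = 3
    bin_hours: float = 1.0
    distance_mode: str = "mean"
    k_min: int = 2
    k_max: int | None = None  # default: min(50, ceil(sqrt(n)))

    def __post_init__(self) -> None:
        if self.distance_mode not in ("mean", "sum"):
            raise ValueError("distance_mode must be 'mean' or 'sum'")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")

    @classmethod
    def from_mapping(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        sections = {}
        if "simulate" in data:
            sim = data.pop("simulate")
            sections["simulate"] = None if sim is None else SimulateConfig.from_mapping(sim)
        if "preprocess" in data:
            sections["preprocess"] = _from_mapping(
                PreprocessParams, _tupled(data.pop("preprocess"), "hough_radius_fractions"), "preprocess"
            )
        if "lbp" in data:
            sections["lbp"] = _from_mapping(LBPParams, data.pop("lbp"), "lbp")
        return _from_mapping(cls, {**data, **sections}, "pipeline")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_mapping(data)

    def to_mapping(self) -> dict[str, Any]:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            if isinstance(obj, (list,)):
                return [convert(v) for v in obj]
            return obj

        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "simulate" and v is not None:
                out[f.name] = {
                    "classes": [
                        {**dataclasses.asdict(spec), "count": count}
                        for spec, count in v.classes
                    ],
                    "growth": dataclasses.asdict(v.growth),
                    "image_size": v.image_size,
                    "folder": v.folder,
                    "rotate_frames": v.rotate_frames,
                    "plate_edge": v.plate_edge,
                }
            else:
                out[f.name] = convert(v)
        return out

    def to_yaml(self, path: Path | str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_mapping(), fh, sort_keys=False)


def _tupled(data: dict[str, Any], *keys: str) -> dict[str, Any]:
    data = dict(data)
    for k in keys:
        if k in data and isinstance(data[k], list):
            data[k] = tuple(data[k])
    return data
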