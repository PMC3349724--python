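"""YAML pipeline configuration.

A config file has one section per stage (sim, segmentation, foci, scoring,
screen) plus top-level acquisition settings.  Unknown keys are rejected —
a typo in a threshold name must not silently fall back to a default.
The canonical form round-trips: write -> read -> write is identity.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ConfigError
from .foci import FociParams
from .score import DistancePool, ScoreParams
from .screen import ScreenParams
from .segment import SegParams
from .simulate import SimParams


def _from_dict(cls, data: Mapping[str, Any] | None):
    data = dict(data or {})
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    # YAML lists arrive as lists; tuple-typed fields want tuples
    for f in fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {cls.__name__}: {exc}") from exc


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in fields(obj)}
    if isinstance(obj, DistancePool):
        return obj.value
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


@dataclass
class PipelineConfig:
    pixel_size_um: float = 0.2
    channel_order: tuple[str, ...] = ("DAPI", "FISH_A", "FISH_B")
    seed: int = 0
    sim: SimParams = field(default_factory=SimParams)
    segmentation: SegParams = field(default_factory=SegParams)
    foci: FociParams = field(default_factory=FociParams)
    scoring: ScoreParams = field(default_factory=ScoreParams)
    screen: ScreenParams = field(default_factory=ScreenParams)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be positive")
        self.channel_order = tuple(self.channel_order)
        if "DAPI" not in self.channel_order:
            raise ConfigError("channel_order must include DAPI")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "sim": SimParams, "segmentation": SegParams, "foci": FociParams,
            "scoring": ScoreParams, "screen": ScreenParams,
        }
        known = set(sections) | {"pixel_size_um", "channel_order", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key in ("pixel_size_um", "seed"):
            if key in data:
                kwargs[key] = data[key]
        if "channel_order" in data:
            kwargs["channel_order"] = tuple(data["channel_order"])
        for key, klass in sections.items():
            if key in data:
                kwargs[key] = _from_dict(klass, data[key])
        cfg = cls(**kwargs)
        # acquisition pixel size flows into the simulator unless overridden
        if "sim" in data and "pixel_size_um" not in (data["sim"] or {}):
            cfg.sim = dataclasses.replace(cfg.sim, pixel_size_um=cfg.pixel_size_um)
        elif "sim" not in data:
            cfg.sim = dataclasses.replace(cfg.sim, pixel_size_um=cfg.pixel_size_um)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        return _to_plain(self)  # type: ignore[return-value]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True,
                           default_flow_style=False)

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
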