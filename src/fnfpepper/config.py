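"""Run configuration.

Every pipeline constant lives here with its field default, so the
zero-flag CLI behavior is the reference configuration: hue band 20-50 deg,
saturation band 90-255, minimum blob size 400 px at 320x240, IoU threshold
0.5, FNF brightness threshold 10.  A YAML file can override any subset;
unknown keys are rejected rather than silently ignored.

Hue and saturation thresholds may be written either on their native scales
(degrees / 8-bit) or as unit fractions (e.g. ``hue_min: 0.0556`` for
20/360): values at or below 1 are interpreted as fractions and converted
at this boundary — internally hue is always degrees and saturation 8-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .detector import DetectorParams
from .evaluation import EvalParams
from .imaging import FNFParams

__all__ = ["RunConfig", "load_config"]

_SCALES = {"hue_min": 360.0, "hue_max": 360.0, "sat_min": 255.0, "sat_max": 255.0}


@dataclass
class RunConfig:
    """Full configuration of one reproducible run."""

    modality: str = "fnf"
    scheme: str = "strict"
    cluster_mode: str = "per_object"
    detector: DetectorParams = field(default_factory=DetectorParams)
    fnf: FNFParams = field(default_factory=FNFParams)
    eval: EvalParams = field(default_factory=EvalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("fnf", "flash", "noflash"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.scheme not in ("strict", "flexible"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.cluster_mode not in ("per_object", "cluster_credit"):
            raise ValueError(f"unknown cluster_mode {self.cluster_mode!r}")


def _build(cls: type, raw: dict[str, Any], context: str) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ValueError(f"unknown config keys in {context}: {sorted(unknown)}")
    converted = {}
    for key, value in raw.items():
        if key in _SCALES and isinstance(value, (int, float)) and value <= 1.0:
            value = value * _SCALES[key]
        converted[key] = value
    return cls(**converted)


def load_config(path: Optional[str | Path] = None, overrides: dict[str, Any] | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Section keys ``detector``, ``fnf`` and ``eval`` map to their parameter
    dataclasses; any other key must be a top-level :class:`RunConfig` field.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update(loaded)
    for key, value in (overrides or {}).items():
        if isinstance(value, dict):
            raw.setdefault(key, {})
            raw[key].update(value)
        elif value is not None:
            raw[key] = value

    sections = {
        "detector": DetectorParams,
        "fnf": FNFParams,
        "eval": EvalParams,
    }
    kwargs: dict[str, Any] = {}
    for name, cls in sections.items():
        if name in raw:
            kwargs[name] = _build(cls, raw.pop(name) or {}, name)
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(raw)
    return RunConfig(**kwargs)
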