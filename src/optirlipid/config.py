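"""Run configuration: one structured document holding every stage's defaults.

Unknown keys are rejected rather than ignored, and every pipeline run writes
its fully resolved configuration next to its outputs so results are
reproducible from the output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .peakfit import FitConfig

CONFIG_VERSION = "1"


@dataclass
class PreprocessConfig:
    amide_anchor: float = 1654.0
    silent_gap: tuple[float, float] = (1780.0, 2030.0)
    min_spectra_per_cell: int = 3


@dataclass
class MetricsConfig:
    absent_as_zero: bool = True  # untagged controls are measurable zeros
    lod_k: float = 3.0  # 3.3 for the ICH convention
    depth_use_fit: bool = True  # fitted azide area (raw trapezoid otherwise)


@dataclass
class ImagingConfig:
    ratio_threshold_frac: float = 0.05
    min_valid_pixels: int = 10
    histogram_bins: int | None = None  # None = Freedman-Diaconis
    histogram_components: int = 1


@dataclass
class StatsConfig:
    alpha: float = 0.05
    welch: bool = False


@dataclass
class RunConfig:
    version: str = CONFIG_VERSION
    seed: int = 0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    # -- (de)serialization ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cfg = cls()
        _apply(cfg, data, path="")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the resolved configuration (for run reports)."""
        blob = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def set_override(self, dotted_key: str, value: str) -> None:
        """Apply a ``section.key=value`` CLI override with YAML-typed value."""
        parts = dotted_key.split(".")
        target = self
        for part in parts[:-1]:
            if not hasattr(target, part):
                raise ConfigError(f"unknown config section {part!r} in {dotted_key!r}")
            target = getattr(target, part)
        leaf = parts[-1]
        if not dataclasses.is_dataclass(target) or leaf not in {
            f.name for f in dataclasses.fields(target)
        }:
            raise ConfigError(f"unknown config key {dotted_key!r}")
        parsed = yaml.safe_load(value)
        if isinstance(getattr(target, leaf), tuple) and isinstance(parsed, list):
            parsed = tuple(parsed)
        setattr(target, leaf, parsed)


def _apply(obj, data: dict, path: str) -> None:
    if not isinstance(data, dict):
        raise ConfigError(f"config section {path or '<root>'} must be a mapping")
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        full = f"{path}{key}"
        if key not in names:
            raise ConfigError(f"unknown config key {full!r}")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and not isinstance(current, type):
            _apply(current, value, path=f"{full}.")
        else:
            if isinstance(current, tuple) and isinstance(value, list):
                value = tuple(value)
            setattr(obj, key, value)


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x
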