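"""Pipeline configuration: a single YAML file, round-tripped losslessly.

Unknown keys are rejected so typos fail loudly; CLI flags override the file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .synthetic_region import RegionConfig

__all__ = ["PipelineConfig"]

_EQUAL_WEIGHTS = {
    "retail": [0.2, 0.2, 0.2, 0.2, 0.2],
    "health": [0.2, 0.2, 0.2, 0.2, 0.2],
    "physical": [0.25, 0.25, 0.25, 0.25],
    "domains": [1 / 3, 1 / 3, 1 / 3],
}


@dataclass
class PipelineConfig:
    """Everything ``ahah run-all`` needs.

    weights: per-domain indicator weight vectors plus the 3-element
    ``domains`` vector; the equal-weight default reproduces the published
    construction.
    """

    region: RegionConfig = field(default_factory=RegionConfig)
    buffer_m: float = 900.0
    green_area_mode: str = "clipped"  # or 'whole_polygon'
    raster_overlap: str = "footprint"  # or 'centre'
    correlation: str = "pearson"  # or 'spearman'
    weights: dict = field(default_factory=lambda: {k: list(v) for k, v in _EQUAL_WEIGHTS.items()})
    log_level: str = "INFO"

    def validate(self) -> None:
        self.region.validate()
        if self.buffer_m <= 0:
            raise ConfigurationError("buffer_m must be positive")
        if self.green_area_mode not in ("clipped", "whole_polygon"):
            raise ConfigurationError(
                f"green_area_mode must be clipped|whole_polygon, got "
                f"'{self.green_area_mode}'"
            )
        if self.raster_overlap not in ("footprint", "centre"):
            raise ConfigurationError(
                f"raster_overlap must be footprint|centre, got '{self.raster_overlap}'"
            )
        if self.correlation not in ("pearson", "spearman"):
            raise ConfigurationError(
                f"correlation must be pearson|spearman, got '{self.correlation}'"
            )
        unknown = set(self.weights) - set(_EQUAL_WEIGHTS)
        if unknown:
            raise ConfigurationError(f"unknown weight groups: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region"] = self.region.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "region" in d:
            d["region"] = RegionConfig.from_dict(d["region"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )
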