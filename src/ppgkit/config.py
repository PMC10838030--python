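"""Run configuration: every under-specified analysis choice in one place.

The config round-trips through YAML unchanged, so a run is fully
reproducible from its config file and seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class FPAConfig:
    mode: str = "per_beat_median"      # per_beat_median | ensemble
    smoothing_window_s: float = 0.05
    smoothing_polyorder: int = 3
    quality_threshold: float = 0.9


@dataclass
class SPARConfig:
    normalize: bool = True
    grid_bins: int = 251
    extent: float = 0.85
    registry_version: str = "v1"


@dataclass
class ClassificationConfig:
    threshold: float = 0.85
    bh_correction: bool = False


@dataclass
class RunConfig:
    window_length_s: float = 60.0
    window_start_s: float = 0.0
    fpa: FPAConfig = field(default_factory=FPAConfig)
    spar: SPARConfig = field(default_factory=SPARConfig)
    classification: ClassificationConfig = field(
        default_factory=ClassificationConfig)
    seed: int = 0

    def to_yaml(self, path) -> Path:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return Path(path)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            return cls(
                window_length_s=raw.get("window_length_s", 60.0),
                window_start_s=raw.get("window_start_s", 0.0),
                fpa=FPAConfig(**raw.get("fpa", {})),
                spar=SPARConfig(**raw.get("spar", {})),
                classification=ClassificationConfig(
                    **raw.get("classification", {})),
                seed=int(raw.get("seed", 0)),
            )
        except TypeError as exc:
            raise ConfigurationError(f"bad config: {exc}") from exc
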