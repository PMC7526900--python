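"""Run configuration: a single YAML-backed, validated settings object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid configuration value; the message names the field."""


@dataclass
class RunConfig:
    """All tunable settings of the pipeline, with the defaults of the method.

    Defaults mirror the reference analysis: 500 kb bins, 10 Mb locus-pair
    cutoff, QC at 1000 contacts and cis/trans ratio 1, topic-grid LDA,
    specificity tests at alpha 0.01 with ratio filter 1.5, gamma cutoff at
    the 99.75th percentile.
    """

    resolution: int = 500_000
    max_distance: int = 10_000_000
    extra_bin: bool = True
    chroms: list[str] | None = None
    min_contacts: int = 1000
    min_cis_trans_ratio: float = 1.0
    n_topics: list[int] = field(default_factory=lambda: [30])
    alpha: float | None = None
    eta: float = 0.1
    iterations: int = 500
    burnin: int = 250
    seed: int = 0
    lda_init: str = "random"
    specificity_alpha: float = 0.01
    specificity_ratio: float = 1.5
    gamma_percentile: float = 99.75
    ice_max_iter: int = 200
    ice_tol: float = 1e-5
    mask_percentile: float = 2.0

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ConfigError(f"resolution must be positive, got {self.resolution}")
        if self.max_distance < self.resolution:
            raise ConfigError(
                f"max_distance ({self.max_distance}) must be >= resolution"
            )
        if not 0 < self.gamma_percentile < 100:
            raise ConfigError(
                f"gamma_percentile must be in (0, 100), got {self.gamma_percentile}"
            )
        if not 0 < self.specificity_alpha < 1:
            raise ConfigError(
                f"specificity_alpha must be in (0, 1), got {self.specificity_alpha}"
            )
        if self.iterations <= self.burnin or self.burnin < 0:
            raise ConfigError("iterations must exceed burnin (burnin >= 0)")
        if not self.n_topics or any(t < 1 for t in self.n_topics):
            raise ConfigError(f"n_topics must be positive integers, got {self.n_topics}")
        if self.lda_init not in ("random", "kmeans"):
            raise ConfigError(f"lda_init must be 'random' or 'kmeans', got {self.lda_init!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
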