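"""Run configuration: every threshold of the analysis in one place."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import yaml


@dataclass(frozen=True)
class RunConfig:
    """Analysis thresholds and run settings.

    Defaults are the analysis' canonical constants: depth filter 100,
    FDR 0.5%, consistency tiers 100/90/80%, coverage 15 crosses with
    3 maize and 5 teosinte parents, D/A class bounds 0.25 / 0.75-1.25,
    Dixon alpha 0.05.
    """

    min_depth: int = 100
    fdr_threshold: float = 0.005
    tier_a: float = 1.0
    tier_b: float = 0.9
    tier_c: float = 0.8
    min_crosses: int = 15
    min_maize: int = 3
    min_teosinte: int = 5
    da_additive_max: float = 0.25
    da_dominant_low: float = 0.75
    da_dominant_high: float = 1.25
    dixon_alpha: float = 0.05
    bootstrap_reps: int = 1000
    seed: int = 0
    n_genes: int = 2000
    reference_line: str = "B73"

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not (0 < self.tier_c <= self.tier_b <= self.tier_a <= 1):
            raise ValueError("tiers must satisfy 0 < C <= B <= A <= 1")
        if not 0 <= self.da_additive_max <= self.da_dominant_low <= self.da_dominant_high:
            raise ValueError("D/A thresholds out of order")
        if not 0 < self.dixon_alpha < 1:
            raise ValueError("dixon_alpha must be in (0, 1)")
        if self.bootstrap_reps < 0 or self.n_genes < 1:
            raise ValueError("bootstrap_reps >= 0 and n_genes >= 1 required")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    def digest(self) -> str:
        """Stable hash of the configuration, for run manifests."""
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
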