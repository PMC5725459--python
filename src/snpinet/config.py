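"""Run configuration.

All pipeline constants live in one dataclass so a whole analysis is
reproducible from a single YAML file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class FilterThresholds:
    """GATK-style hard-filter thresholds for SNP call sets.

    A variant is removed when QD < qd, MQ < mq, FS > fs, or QUAL < qual
    (all comparisons strict).  A missing INFO field never fires its clause.
    """

    qd: float = 5.0
    mq: float = 40.0
    fs: float = 200.0
    qual: float = 30.0

    def __post_init__(self) -> None:
        for name in ("qd", "mq", "fs", "qual"):
            if getattr(self, name) < 0:
                raise ValueError(f"filter threshold {name} must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    """Constants for a full pipeline run.

    Parameters
    ----------
    restart_probability
        Restart probability of the random walk with restart; high values
        keep the extended protein set close to the seeds.
    top_fraction
        Fraction of nonzero-scoring proteins kept as the extended set.
    string_score_threshold
        Minimum interaction score for an edge to count as a credible
        protein-protein interaction (inclusive).
    n_randomizations
        Number of resamples for the branch-change randomization test.
    bonferroni_alpha
        Family-wise significance level for term enrichment.
    weighted_propagation
        Whether the walk uses edge scores as weights (binary otherwise).
    threshold_before_propagation
        If True, drop sub-threshold edges before propagation as well as
        before the interaction-evolution analysis.
    """

    restart_probability: float = 0.95
    top_fraction: float = 0.05
    string_score_threshold: float = 0.7
    n_randomizations: int = 10_000
    bonferroni_alpha: float = 0.05
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    weighted_propagation: bool = True
    threshold_before_propagation: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_probability <= 1.0:
            raise ValueError("restart_probability must be in (0, 1]")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0.0 <= self.string_score_threshold <= 1.0:
            raise ValueError("string_score_threshold must be in [0, 1]")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be positive")
        if not 0.0 < self.bonferroni_alpha <= 1.0:
            raise ValueError("bonferroni_alpha must be in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.pop("filter_thresholds", None)
        kwargs = dict(raw)
        if thr is not None:
            kwargs["filter_thresholds"] = FilterThresholds(**thr)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
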