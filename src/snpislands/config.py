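"""Tunable thresholds for every pipeline stage.

Defaults reproduce the published panel-design parameters: impactful SNPs are
those with global alternate-allele frequency in [0.30, 0.70]; conserved
(low-variance) flanks tolerate only near-fixed SNPs (AF <= 0.5% or >= 99.5%);
an island core may span at most 400 bp and must be flanked by at least 150 bp
of conserved sequence on each side.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import TextIO

import yaml
from scipy.stats import norm


@dataclass(frozen=True)
class ScannerConfig:
    """Thresholds for the three-state island scanner."""

    impactful_lo: float = 0.30
    impactful_hi: float = 0.70
    conserved_max_af: float = 0.005
    conserved_min_af_hi: float = 0.995
    max_island_len: int = 400
    min_flank_len: int = 150
    min_impactful: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.impactful_lo < self.impactful_hi <= 1.0):
            raise ValueError("require 0 <= impactful_lo < impactful_hi <= 1")
        if self.conserved_max_af >= self.impactful_lo:
            raise ValueError("conserved_max_af must lie below impactful_lo")
        if self.conserved_min_af_hi <= self.impactful_hi:
            raise ValueError("conserved_min_af_hi must lie above impactful_hi")
        if self.max_island_len <= 0 or self.min_flank_len <= 0:
            raise ValueError("lengths must be positive")
        if self.min_impactful < 1:
            raise ValueError("min_impactful must be >= 1")


@dataclass(frozen=True)
class SequenceFilterConfig:
    """Short-read chemistry filters: homopolymer clusters and tandem repeats.

    A window of ``window_len`` bp is slid one base at a time; runs of a single
    nucleotide of length >= ``cluster_min_run`` inside the window are clusters,
    and a window whose clusters of one nucleotide total >= ``cluster_total``
    bases rejects the target.  A unit of ``unit_min``..``unit_max`` bp repeated
    strictly more than ``max_consecutive_repeats`` times consecutively also
    rejects the target.
    """

    window_len: int = 20
    cluster_min_run: int = 4
    cluster_total: int = 10
    unit_min: int = 2
    unit_max: int = 7
    max_consecutive_repeats: int = 5

    def __post_init__(self) -> None:
        if self.window_len < self.cluster_min_run:
            raise ValueError("window_len must be >= cluster_min_run")
        if self.cluster_total > self.window_len:
            raise ValueError("cluster_total cannot exceed window_len")
        if not (2 <= self.unit_min <= self.unit_max):
            raise ValueError("require 2 <= unit_min <= unit_max")
        if self.max_consecutive_repeats < 1:
            raise ValueError("max_consecutive_repeats must be >= 1")


@dataclass(frozen=True)
class UniquenessConfig:
    """Primer-feasibility filter: exact genome-wide k-mer uniqueness.

    A flank position is uniquely anchored when its ``seed_len``-mer occurs
    exactly once in the genome (counting reverse-complement occurrences);
    maximal anchored runs form unique stretches, which qualify when strictly
    longer than ``min_unique_stretch`` bp.
    """

    seed_len: int = 15
    min_unique_stretch: int = 25

    def __post_init__(self) -> None:
        if self.seed_len < 8:
            raise ValueError("seed_len must be >= 8")
        if self.min_unique_stretch < self.seed_len:
            raise ValueError("min_unique_stretch must be >= seed_len")


@dataclass(frozen=True)
class CiConfig:
    """Binomial-proportion confidence interval and zygosity-zone settings.

    The interval is the normal-approximation (Wald) interval p +/- z*sigma_p
    with sigma_p = sqrt(p(1-p)/n), guarded by the large-sample criterion
    n*p*(1-p) >= ``normal_criterion_min``.  Pure-homozygote evidence
    (p exactly 0 or 1) can never satisfy that criterion; such sites receive a
    degenerate point interval when depth reaches ``degenerate_min_depth``.
    """

    confidence_level: float = 0.95
    normal_criterion_min: float = 10.0
    hom_var_zone: tuple[float, float] = (0.0, 0.1)
    het_zone: tuple[float, float] = (0.4, 0.6)
    hom_ref_zone: tuple[float, float] = (0.9, 1.0)
    degenerate_min_depth: int = 20

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence_level < 1.0):
            raise ValueError("confidence_level must lie in (0, 1)")
        zones = [self.hom_var_zone, self.het_zone, self.hom_ref_zone]
        for lo, hi in zones:
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("zone bounds must satisfy 0 <= lo <= hi <= 1")
        if not (self.hom_var_zone[1] < self.het_zone[0] < self.het_zone[1] < self.hom_ref_zone[0]):
            raise ValueError("zones must be disjoint and ordered")

    @property
    def z(self) -> float:
        """Two-sided standard-normal critical value Z_{alpha/2} (1.96 at CL 0.95)."""
        alpha = 1.0 - self.confidence_level
        return float(norm.ppf(1.0 - alpha / 2.0))


@dataclass(frozen=True)
class RunConfig:
    """Bundle of all stage configurations, (de)serializable as YAML."""

    scanner: ScannerConfig = field(default_factory=ScannerConfig)
    sequence_filter: SequenceFilterConfig = field(default_factory=SequenceFilterConfig)
    uniqueness: UniquenessConfig = field(default_factory=UniquenessConfig)
    ci: CiConfig = field(default_factory=CiConfig)

    def to_yaml(self, stream: TextIO) -> None:
        yaml.safe_dump(
            {
                "scanner": dataclasses.asdict(self.scanner),
                "sequence_filter": dataclasses.asdict(self.sequence_filter),
                "uniqueness": dataclasses.asdict(self.uniqueness),
                "ci": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in dataclasses.asdict(self.ci).items()
                },
            },
            stream,
            sort_keys=True,
        )

    @classmethod
    def from_yaml(cls, stream: TextIO | str) -> "RunConfig":
        raw = yaml.safe_load(stream) or {}
        ci_raw = dict(raw.get("ci", {}))
        for key in ("hom_var_zone", "het_zone", "hom_ref_zone"):
            if key in ci_raw:
                ci_raw[key] = tuple(ci_raw[key])
        return cls(
            scanner=ScannerConfig(**raw.get("scanner", {})),
            sequence_filter=SequenceFilterConfig(**raw.get("sequence_filter", {})),
            uniqueness=UniquenessConfig(**raw.get("uniqueness", {})),
            ci=CiConfig(**ci_raw),
        )
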