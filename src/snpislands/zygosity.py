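"""Zygosity calling from per-SNP reference-call counts.

At a biallelic SNP sequenced to depth n with x reads calling the reference
base, the sample proportion p = x/n estimates the reference-allele dosage:
near 1 for homozygous reference, near 0.5 for heterozygous, near 0 for
homozygous variant.  A normal-approximation (Wald) confidence interval
p +/- Z_{alpha/2} * sqrt(p(1-p)/n) is computed whenever the large-sample
criterion n*p*(1-p) >= 10 holds, and the call is made by overlap of that
interval with the three zygosity zones (0.9-1.0 reference, 0.4-0.6
heterozygous, 0-0.1 variant).  Intervals overlapping no zone are
``out_of_zone`` — the signature of multi-contributor (mixed) DNA, whose
discordant genotypes produce allele fractions near 0.25/0.75.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import CiConfig

logger = logging.getLogger(__name__)

CODE_BY_CALL = {"hom_ref": 1, "het": 2, "hom_var": 3}


@dataclass(frozen=True)
class SnpEvidence:
    """Reference-call count x out of depth n at one SNP for one sample."""

    sample: str
    chrom: str
    pos: int
    x: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.x <= self.n):
            raise ValueError(f"require 0 <= x <= n, got x={self.x}, n={self.n}")


@dataclass(frozen=True)
class ZygosityCall:
    """Proportion, interval, zone classification and 1/2/3 code for one SNP."""

    evidence: SnpEvidence
    p: float | None
    ci_low: float | None
    ci_high: float | None
    call: str  # hom_ref | het | hom_var | no_call | ambiguous | out_of_zone
    code: int | None

    @property
    def has_interval(self) -> bool:
        return self.ci_low is not None


def proportion_ci(
    x: int, n: int, config: CiConfig
) -> tuple[float, tuple[float, float] | None]:
    """Sample proportion and Wald interval (or None when not computable).

    The interval is computed only when n*p*(1-p) >= ``normal_criterion_min``;
    pure p in {0, 1} — which can never meet that criterion — receives a
    degenerate point interval once depth reaches ``degenerate_min_depth``.
    """
    if n < 1:
        raise ValueError("depth n must be >= 1")
    if not (0 <= x <= n):
        raise ValueError("require 0 <= x <= n")
    p = x / n
    if n * p * (1.0 - p) >= config.normal_criterion_min:
        half = config.z * math.sqrt(p * (1.0 - p) / n)
        return p, (max(0.0, p - half), min(1.0, p + half))
    if p in (0.0, 1.0) and n >= config.degenerate_min_depth:
        return p, (p, p)
    return p, None


def classify(
    p: float, interval: tuple[float, float] | None, config: CiConfig
) -> str:
    """Zone-overlap classification of a proportion interval."""
    if interval is None:
        return "no_call"
    lo, hi = interval
    overlaps = [
        call
        for call, (zlo, zhi) in (
            ("hom_var", config.hom_var_zone),
            ("het", config.het_zone),
            ("hom_ref", config.hom_ref_zone),
        )
        if lo <= zhi and hi >= zlo
    ]
    if len(overlaps) == 1:
        return overlaps[0]
    return "ambiguous" if overlaps else "out_of_zone"


def call_evidence(evidence: SnpEvidence, config: CiConfig) -> ZygosityCall:
    """Full per-SNP call; zero depth yields a no_call with no proportion."""
    if evidence.n == 0:
        return ZygosityCall(evidence, None, None, None, "no_call", None)
    p, interval = proportion_ci(evidence.x, evidence.n, config)
    call = classify(p, interval, config)
    lo, hi = interval if interval is not None else (None, None)
    return ZygosityCall(evidence, p, lo, hi, call, CODE_BY_CALL.get(call))


def mixture_flag(
    profile_calls: Sequence[ZygosityCall], threshold: float = 0.2
) -> tuple[float | None, bool | None]:
    """Fraction of interval-bearing calls outside all zones, and the flag.

    Multi-contributor DNA scatters allele fractions across the whole [0, 1]
    range, so a high out-of-zone (or ambiguous) fraction flags a mixture.
    Returns (None, None) when no call carries an interval.
    """
    if not profile_calls:
        raise ValueError("profile_calls must be non-empty")
    with_interval = [c for c in profile_calls if c.has_interval]
    if not with_interval:
        logger.warning("no SNP with a confidence interval; mixture flag unavailable")
        return None, None
    n_out = sum(1 for c in with_interval if c.call in ("out_of_zone", "ambiguous"))
    fraction = n_out / len(with_interval)
    return fraction, fraction > threshold


# ---------------------------------------------------------------------------
# tabular interface

COUNTS_COLUMNS = ["sample", "chrom", "pos", "ref_calls", "depth"]


def read_counts_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = [c for c in COUNTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    return df


def call_table(counts: pd.DataFrame, config: CiConfig) -> pd.DataFrame:
    """Call every row of a (sample, chrom, pos, ref_calls, depth) table."""
    rows = []
    for rec in counts.itertuples(index=False):
        ev = SnpEvidence(str(rec.sample), str(rec.chrom), int(rec.pos),
                         int(rec.ref_calls), int(rec.depth))
        c = call_evidence(ev, config)
        rows.append(
            (ev.sample, ev.chrom, ev.pos, ev.x, ev.n, c.p, c.ci_low, c.ci_high,
             c.call, c.code)
        )
    return pd.DataFrame(
        rows,
        columns=COUNTS_COLUMNS[:3] + ["ref_calls", "depth", "p", "ci_low",
                                      "ci_high", "call", "code"],
    )


def write_call_table(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False, float_format="%.6g")
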