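"""Sequencing-chemistry suitability filters for island target windows.

Short-read chemistries lose phasing accuracy over homopolymer stretches and
short tandem repeats, so targets containing either are discarded before
primer design:

* **Homopolymer clusters** — a 20 bp window slides one base at a time; inside
  a window, maximal runs of one nucleotide of length >= 4 are "clusters", and
  if the clusters of any single nucleotide total >= 10 bases within a window
  the target is rejected.  Runs truncated by the window edge count at their
  truncated length.
* **Tandem repeats** — a unit of 2-7 bp repeated strictly more than 5 times
  consecutively rejects the target.  Detection compares the sequence to
  itself under each offset u in 2..7: a maximal run of L positions with
  s[i] == s[i+u] is a stretch of period u containing floor(L/u) + 1
  consecutive copies of its leading u-mer.  Units whose primitive root is a
  single base (pure homopolymer content) are left to the homopolymer rule.

N bases match nothing, not even another N, so they break runs and units.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .config import SequenceFilterConfig
from .genome_io import ReferenceGenome


@dataclass(frozen=True)
class FilterHit:
    """Location evidence for a rejection."""

    reason: str  # "homopolymer" or "tandem_repeat"
    start: int  # 0-based offset into the scanned sequence
    end: int  # 0-based exclusive
    detail: str


def _runs(sequence: str) -> list[tuple[str, int, int]]:
    """Maximal single-character runs as (char, start, end) with end exclusive."""
    runs = []
    i = 0
    n = len(sequence)
    while i < n:
        j = i + 1
        while j < n and sequence[j] == sequence[i]:
            j += 1
        runs.append((sequence[i], i, j))
        i = j
    return runs


def find_homopolymer_cluster(
    sequence: str, config: SequenceFilterConfig
) -> FilterHit | None:
    """First window whose single-nucleotide clusters total >= cluster_total."""
    n = len(sequence)
    w = config.window_len
    runs = [r for r in _runs(sequence) if r[0] != "N"]
    if not runs:
        return None
    starts = range(max(1, n - w + 1))
    first_run = 0
    for ws in starts:
        we = min(ws + w, n)  # exclusive
        while first_run < len(runs) and runs[first_run][2] <= ws:
            first_run += 1
        totals: dict[str, int] = {}
        k = first_run
        while k < len(runs) and runs[k][1] < we:
            base, rs, re = runs[k]
            clipped = min(re, we) - max(rs, ws)
            if clipped >= config.cluster_min_run:
                totals[base] = totals.get(base, 0) + clipped
            k += 1
        for base, total in totals.items():
            if total >= config.cluster_total:
                return FilterHit(
                    "homopolymer", ws, we, f"{base}-clusters total {total} in window"
                )
    return None


def homopolymer_cluster_reject(sequence: str, config: SequenceFilterConfig) -> bool:
    """True when the target must be rejected for homopolymer clustering."""
    return find_homopolymer_cluster(sequence, config) is not None


def _primitive_root_len(unit: str) -> int:
    """Length of the shortest string whose repetition yields ``unit``."""
    u = len(unit)
    for d in range(1, u + 1):
        if u % d == 0 and unit == unit[:d] * (u // d):
            return d
    return u  # unreachable


def find_tandem_repeat(
    sequence: str, config: SequenceFilterConfig
) -> FilterHit | None:
    """First unit of unit_min..unit_max bp repeated > max_consecutive_repeats."""
    n = len(sequence)
    max_rep = config.max_consecutive_repeats
    for u in range(config.unit_min, config.unit_max + 1):
        if (max_rep + 1) * u > n:
            continue
        i = 0
        limit = n - u
        while i < limit:
            a, b = sequence[i], sequence[i + u]
            if a != b or a == "N":
                i += 1
                continue
            j = i
            while j < limit:
                a, b = sequence[j], sequence[j + u]
                if a != b or a == "N":
                    break
                j += 1
            run_len = j - i  # positions with s[k] == s[k+u]
            count = run_len // u + 1
            if count > max_rep:
                unit = sequence[i : i + u]
                if _primitive_root_len(unit) >= config.unit_min:
                    return FilterHit(
                        "tandem_repeat",
                        i,
                        i + count * u,
                        f"unit {unit} x{count}",
                    )
            i = j + 1
    return None


def tandem_repeat_reject(sequence: str, config: SequenceFilterConfig) -> bool:
    """True when the target must be rejected for a short tandem repeat."""
    return find_tandem_repeat(sequence, config) is not None


def filter_targets(
    islands: Iterable,
    genome: ReferenceGenome,
    config: SequenceFilterConfig,
) -> tuple[list, list[tuple[object, FilterHit]]]:
    """Partition islands into (kept, rejected-with-evidence).

    Each island's full target window (flank I start through flank II end) is
    scanned, since the whole amplicon is sequenced.  Out-of-bounds coordinates
    are a hard error.
    """
    kept = []
    rejected = []
    for isl in islands:
        seq = genome.subsequence(isl.chrom, isl.flank1_start, isl.flank2_end)
        hit = find_homopolymer_cluster(seq, config)
        if hit is None:
            hit = find_tandem_repeat(seq, config)
        if hit is None:
            kept.append(isl)
        else:
            rejected.append((isl, hit))
    return kept, rejected
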