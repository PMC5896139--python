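"""Three-state SNP-island scanner.

The scanner walks each chromosome left to right looking for a compact cluster
of intermediate-frequency ("impactful") SNPs bracketed by conserved sequence:

* **Low-Variance Segment I** — a run of at least ``min_flank_len`` bases
  containing no impactful or relevant SNP (near-fixed SNPs are invisible).
* **High-Variance Segment** — anchored at the first impactful SNP after an
  established LV1; impactful (and any intervening relevant) SNPs are absorbed
  while the core, first to last absorbed SNP, stays within
  ``max_island_len`` bases.
* **Low-Variance Segment II** — once ``min_impactful`` SNPs are counted the
  scanner seeks a clean run of ``min_flank_len`` bases immediately after the
  last in-core SNP; any SNP breaking that run is absorbed into the core if the
  core still fits, otherwise the candidate fails and scanning regresses to the
  position after the failed anchor.

On success the verified LV2 run is immediately eligible to serve as the next
island's LV1.  N runs in the reference (when a genome is supplied) break
low-variance segments: a flank may not span unsequenced bases.
"""

from __future__ import annotations

import enum
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .config import ScannerConfig
from .genome_io import AlleleFrequencyRecord, ReferenceGenome


class SnpClass(str, enum.Enum):
    """Scanner-relevant classification of a SNP by global frequency."""

    IMPACTFUL = "impactful"
    RELEVANT = "relevant"
    IGNORABLE = "ignorable"


@dataclass(frozen=True)
class SnpIsland:
    """A discovered target: high-variance core plus verified conserved flanks.

    All coordinates are 1-based closed.  The core runs from the first to the
    last absorbed SNP; ``flank1_start``/``flank2_end`` bound the verified
    minimum-length conserved flanks.
    """

    chrom: str
    core_start: int
    core_end: int
    flank1_start: int
    flank2_end: int
    impactful_snps: list[AlleleFrequencyRecord] = field(default_factory=list)
    other_relevant_snps: list[AlleleFrequencyRecord] = field(default_factory=list)

    @property
    def core_length(self) -> int:
        return self.core_end - self.core_start + 1

    @property
    def window(self) -> tuple[int, int]:
        """Full target window (flank I start to flank II end), 1-based closed."""
        return (self.flank1_start, self.flank2_end)


def classify_snp(record: AlleleFrequencyRecord, config: ScannerConfig) -> SnpClass:
    """Classify by AF: impactful in [lo, hi]; ignorable when near-fixed."""
    if config.impactful_lo <= record.af <= config.impactful_hi:
        return SnpClass.IMPACTFUL
    if record.af <= config.conserved_max_af or record.af >= config.conserved_min_af_hi:
        return SnpClass.IGNORABLE
    return SnpClass.RELEVANT


def _n_runs(sequence: str) -> list[tuple[int, int]]:
    """1-based closed intervals of N bases."""
    runs = []
    start = None
    for i, base in enumerate(sequence, start=1):
        if base == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(sequence)))
    return runs


def scan_chromosome(
    records: Sequence[AlleleFrequencyRecord],
    chrom_length: int,
    config: ScannerConfig,
    sequence: str | None = None,
) -> list[SnpIsland]:
    """Run the three-state scan over one chromosome's sorted SNP records."""
    if records:
        positions_in = [r.pos for r in records]
        if any(b < a for a, b in zip(positions_in, positions_in[1:])):
            raise ValueError("records must be sorted by position")
        if positions_in[-1] > chrom_length:
            raise ValueError("record position beyond chromosome length")
        chrom = records[0].chrom
        if any(r.chrom != chrom for r in records):
            raise ValueError("scan_chromosome expects records from one chromosome")

    # events: SNPs that break low-variance segments (impactful or relevant)
    events = [
        (r, classify_snp(r, config))
        for r in records
        if classify_snp(r, config) is not SnpClass.IGNORABLE
    ]
    positions = [r.pos for r, _ in events]
    n_run_starts: list[int] = []
    n_run_ends: list[int] = []
    if sequence is not None:
        if len(sequence) != chrom_length:
            raise ValueError("sequence length disagrees with chrom_length")
        for s, e in _n_runs(sequence):
            n_run_starts.append(s)
            n_run_ends.append(e)

    def window_clean(lo: int, hi: int) -> bool:
        """No breaking SNP and no N base in 1-based closed [lo, hi]."""
        if lo < 1 or hi > chrom_length:
            return False
        i = bisect_left(positions, lo)
        if i < len(positions) and positions[i] <= hi:
            return False
        # an N run [s, e] overlaps iff s <= hi and e >= lo
        j = bisect_right(n_run_starts, hi) - 1
        return not (j >= 0 and n_run_ends[j] >= lo)

    flank = config.min_flank_len
    islands: list[SnpIsland] = []
    idx = 0
    while idx < len(events):
        record, cls = events[idx]
        if cls is not SnpClass.IMPACTFUL or not window_clean(
            record.pos - flank, record.pos - 1
        ):
            idx += 1
            continue

        # high-variance segment anchored here; absorb events greedily
        anchor = record.pos
        last = idx
        n_impactful = 1
        emitted = False
        while True:
            core_end = events[last][0].pos
            if n_impactful >= config.min_impactful and window_clean(
                core_end + 1, core_end + flank
            ):
                members = events[idx : last + 1]
                islands.append(
                    SnpIsland(
                        chrom=record.chrom,
                        core_start=anchor,
                        core_end=core_end,
                        flank1_start=anchor - flank,
                        flank2_end=core_end + flank,
                        impactful_snps=[
                            r for r, c in members if c is SnpClass.IMPACTFUL
                        ],
                        other_relevant_snps=[
                            r for r, c in members if c is SnpClass.RELEVANT
                        ],
                    )
                )
                idx = last + 1
                emitted = True
                break
            nxt = last + 1
            if nxt >= len(events):
                break
            if events[nxt][0].pos - anchor + 1 > config.max_island_len:
                break
            last = nxt
            if events[nxt][1] is SnpClass.IMPACTFUL:
                n_impactful += 1
        if not emitted:
            # regression: resume at the event after the failed anchor
            idx += 1
    return islands


def scan_genome(
    records_by_chrom: Mapping[str, Sequence[AlleleFrequencyRecord]],
    config: ScannerConfig,
    genome: ReferenceGenome | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[SnpIsland]:
    """Scan every chromosome; lengths come from the genome when supplied."""
    islands: list[SnpIsland] = []
    for chrom in records_by_chrom:
        recs = records_by_chrom[chrom]
        if genome is not None:
            length = genome.length(chrom)
            seq = genome.sequence(chrom)
        else:
            if chrom_lengths is None or chrom not in chrom_lengths:
                raise ValueError(
                    f"no genome and no length supplied for chromosome {chrom!r}"
                )
            length = chrom_lengths[chrom]
            seq = None
        islands.extend(scan_chromosome(recs, length, config, sequence=seq))
    return islands


def categorize_islands(islands: Iterable[SnpIsland]) -> dict[str, int]:
    """Tally islands by impactful-SNP count: '5+', '4', '3' (others verbatim)."""
    counts: dict[str, int] = {"5+": 0, "4": 0, "3": 0}
    for isl in islands:
        k = len(isl.impactful_snps)
        key = "5+" if k >= 5 else str(k)
        counts[key] = counts.get(key, 0) + 1
    return counts
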