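"""Primer-feasibility filtering by exact genome-wide k-mer uniqueness.

A primer can only amplify its intended target if its binding site occurs
nowhere else in the genome.  The published workflow established this with a
BLASTn similarity search; here the criterion is operationalized as exact
canonical k-mer uniqueness: a flank position is *uniquely anchored* when the
15-mer starting there occurs exactly once genome-wide, counting a k-mer and
its reverse complement as one (a duplicated site on the opposite strand still
mis-primes).  Maximal runs of anchored positions define unique stretches; an
island survives when each flank carries at least one stretch strictly longer
than 25 bp.  Exact matching is stricter than BLAST about near-identical
duplications and blind to diverged paralogs; the trade-off is determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .config import UniquenessConfig
from .genome_io import ReferenceGenome

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class UniqueStretch:
    """A maximal genome-unique run within one island flank (1-based closed)."""

    chrom: str
    start: int
    end: int
    flank_side: str  # "I" or "II"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class KmerIndex:
    """Occurrence counts of canonical k-mers over a whole genome.

    k-mers containing N are excluded.  A k-mer and its reverse complement
    share a single count.
    """

    def __init__(self, genome: ReferenceGenome, k: int):
        if k < 1:
            raise ValueError("k must be positive")
        if all(genome.length(c) < k for c in genome.chromosomes):
            raise ValueError(f"k={k} exceeds every chromosome length")
        self.k = k
        counts: dict[str, int] = {}
        for chrom in genome.chromosomes:
            seq = genome.sequence(chrom)
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if not _ACGT.issuperset(kmer):
                    continue
                key = canonical(kmer)
                counts[key] = counts.get(key, 0) + 1
        self._counts = counts

    def count(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        return self._counts.get(canonical(kmer), 0)


def build_kmer_index(genome: ReferenceGenome, k: int) -> KmerIndex:
    return KmerIndex(genome, k)


def unique_stretches(
    flank_sequence: str,
    flank_coords: tuple[int, int],
    index: KmerIndex,
    config: UniquenessConfig,
    chrom: str = "",
    flank_side: str = "I",
) -> list[UniqueStretch]:
    """Maximal unique stretches strictly longer than ``min_unique_stretch``.

    ``flank_coords`` is the (start, end) 1-based closed location of the flank
    on ``chrom``; the index must have been built with k = seed_len over the
    genome containing that flank.
    """
    k = index.k
    if k != config.seed_len:
        raise ValueError("index k does not match config.seed_len")
    n = len(flank_sequence)
    if n != flank_coords[1] - flank_coords[0] + 1:
        raise ValueError("flank sequence length disagrees with its coordinates")
    if n < k:
        return []
    anchored = [
        index.count(flank_sequence[i : i + k]) == 1
        if _ACGT.issuperset(flank_sequence[i : i + k])
        else False
        for i in range(n - k + 1)
    ]
    stretches: list[UniqueStretch] = []
    i = 0
    while i < len(anchored):
        if not anchored[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(anchored) and anchored[j + 1]:
            j += 1
        length = (j - i) + k  # run of (j-i+1) anchors covers run+k-1 bases
        if length > config.min_unique_stretch:
            stretches.append(
                UniqueStretch(
                    chrom=chrom,
                    start=flank_coords[0] + i,
                    end=flank_coords[0] + j + k - 1,
                    flank_side=flank_side,
                )
            )
        i = j + 1
    return stretches


def feasibility_filter(
    islands: Iterable,
    genome: ReferenceGenome,
    config: UniquenessConfig,
    index: KmerIndex | None = None,
) -> tuple[list, list[tuple[object, str]], dict[int, list[UniqueStretch]]]:
    """Keep islands whose both flanks carry a qualifying unique stretch.

    Returns (kept, rejected-with-reason, stretches-by-kept-island-index),
    where the reason names the failing flank.  The k-mer index is built once
    over the genome unless one is supplied.
    """
    islands = list(islands)
    if index is None:
        index = KmerIndex(genome, config.seed_len)
    kept: list = []
    rejected: list[tuple[object, str]] = []
    stretches_by_island: dict[int, list[UniqueStretch]] = {}
    for isl in islands:
        f1 = (isl.flank1_start, isl.core_start - 1)
        f2 = (isl.core_end + 1, isl.flank2_end)
        s1 = unique_stretches(
            genome.subsequence(isl.chrom, *f1), f1, index, config, isl.chrom, "I"
        )
        s2 = unique_stretches(
            genome.subsequence(isl.chrom, *f2), f2, index, config, isl.chrom, "II"
        )
        if s1 and s2:
            stretches_by_island[len(kept)] = s1 + s2
            kept.append(isl)
        else:
            sides = [side for side, s in (("I", s1), ("II", s2)) if not s]
            rejected.append((isl, "no unique stretch in flank " + "+".join(sides)))
    return kept, rejected, stretches_by_island
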