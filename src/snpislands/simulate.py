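"""Seeded synthetic data: genomes with planted SNP islands, allele-frequency
VCFs, and genotype-dependent read-count tables.

The generator emulates the study conditions the pipeline was designed for:
clusters of intermediate-frequency SNPs (global AF uniform in [0.30, 0.70])
planted inside cores of at most 400 bp, surrounded by conserved flanks, with
background SNPs elsewhere across the full frequency spectrum.  Read counts
per sample per SNP follow genotype-dependent binomials — the reference-call
probability is 1-eps for homozygous reference, 0.5 for heterozygous and eps
for homozygous variant, with eps the per-base error rate — and two-contributor
mixtures average the contributors' probabilities at the stated ratio.
Genotypes are drawn under Hardy-Weinberg equilibrium from the population AF.

Everything is driven by one integer seed; identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_io import (
    AlleleFrequencyRecord,
    ReferenceGenome,
    write_fasta,
    write_islands_bed,
)
from .scanner import SnpIsland

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class PlantedIsland:
    """Ground-truth island: first impactful SNP at core_start, last at
    core_start + core_span - 1, n_impactful SNPs total."""

    chrom: str
    core_start: int
    n_impactful: int
    core_span: int

    def __post_init__(self) -> None:
        if self.n_impactful < 1 or self.core_span < self.n_impactful:
            raise ValueError("core_span must fit n_impactful distinct positions")

    @property
    def core_end(self) -> int:
        return self.core_start + self.core_span - 1


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic dataset."""

    seed: int
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 12000, "chr2": 12000}
    )
    islands: tuple[PlantedIsland, ...] = ()
    background_density: float = 0.002  # background SNPs per bp
    error_rate: float = 0.005  # per-base miscall probability
    mean_depth: float = 100.0
    mixture_ratio: tuple[float, float] = (0.5, 0.5)
    min_flank_len: int = 150
    max_island_len: int = 400

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must lie in [0, 0.05]")
        by_chrom: dict[str, list[PlantedIsland]] = {}
        for isl in self.islands:
            if isl.chrom not in self.chrom_lengths:
                raise ValueError(f"island on unknown chromosome {isl.chrom!r}")
            if isl.core_span > self.max_island_len:
                raise ValueError("planted core exceeds max_island_len")
            if (
                isl.core_start - self.min_flank_len < 1
                or isl.core_end + self.min_flank_len > self.chrom_lengths[isl.chrom]
            ):
                raise ValueError("planted island flanks exceed chromosome bounds")
            by_chrom.setdefault(isl.chrom, []).append(isl)
        for chrom, isls in by_chrom.items():
            isls = sorted(isls, key=lambda i: i.core_start)
            for a, b in zip(isls, isls[1:]):
                if b.core_start - a.core_end - 1 < 2 * self.min_flank_len:
                    raise ValueError(
                        f"planted islands on {chrom} closer than twice the flank length"
                    )


def default_spec(seed: int) -> SimulationSpec:
    """Ten planted islands (mixed 3/4/5-SNP) across two 12 kb chromosomes."""
    islands = []
    sizes = [5, 4, 3, 5, 3, 4, 3, 5, 3, 4]
    spans = [320, 260, 180, 390, 120, 240, 60, 350, 200, 280]
    starts = [1000, 3200, 5400, 7600, 9800]
    k = 0
    for chrom in ("chr1", "chr2"):
        for start in starts:
            islands.append(PlantedIsland(chrom, start, sizes[k], spans[k]))
            k += 1
    return SimulationSpec(seed=seed, islands=tuple(islands))


def _planted_positions(
    rng: np.random.Generator, isl: PlantedIsland, min_flank_len: int
) -> np.ndarray:
    """SNP positions spanning the core with every consecutive gap shorter
    than the flank length, so a scan cannot close an island early inside
    the planted span."""
    k = isl.n_impactful
    if k == 1:
        return np.array([isl.core_start])
    if isl.core_span == k:
        return np.arange(isl.core_start, isl.core_end + 1)
    for _ in range(1000):
        inner = rng.choice(
            np.arange(isl.core_start + 1, isl.core_end), size=k - 2, replace=False
        )
        pos = np.concatenate(([isl.core_start], np.sort(inner), [isl.core_end]))
        if np.diff(pos).max() < min_flank_len:
            return pos
    # evenly spaced fallback (feasible whenever span <= (k-1)*(flank-1))
    pos = np.linspace(isl.core_start, isl.core_end, num=k).round().astype(int)
    if np.diff(pos).max() >= min_flank_len:
        raise ValueError(
            f"core span {isl.core_span} too wide for {k} SNPs with gaps < {min_flank_len}"
        )
    return pos


def _draw_background_af(rng: np.random.Generator, size: int) -> np.ndarray:
    """Mixed AF spectrum: mostly near-fixed, some relevant, a few impactful."""
    kind = rng.choice(5, size=size, p=[0.45, 0.20, 0.15, 0.10, 0.10])
    af = np.empty(size)
    af[kind == 0] = rng.uniform(0.0, 0.005, (kind == 0).sum())  # rare
    af[kind == 1] = rng.uniform(0.995, 1.0, (kind == 1).sum())  # near-fixed alt
    af[kind == 2] = rng.uniform(0.006, 0.29, (kind == 2).sum())  # relevant low
    af[kind == 3] = rng.uniform(0.71, 0.994, (kind == 3).sum())  # relevant high
    af[kind == 4] = rng.uniform(0.30, 0.70, (kind == 4).sum())  # impactful
    return af


def simulate_genome_and_vcf(
    spec: SimulationSpec, out_dir: str | Path | None = None
) -> tuple[ReferenceGenome, dict[str, list[AlleleFrequencyRecord]], list[SnpIsland]]:
    """Random genome with planted islands; optionally write FASTA/VCF/BED.

    Returns the genome, per-chromosome sorted allele-frequency records, and
    the truth islands (coordinates the scanner should recover exactly).
    Background SNPs are kept out of a guard zone of max_island_len +
    min_flank_len bases around each planted core so that no background SNP
    can join or shadow a planted island.
    """
    rng = np.random.default_rng(spec.seed)
    sequences = {
        chrom: "".join(rng.choice(_BASES, size=length))
        for chrom, length in spec.chrom_lengths.items()
    }
    genome = ReferenceGenome(sequences)

    records: dict[str, list[AlleleFrequencyRecord]] = {
        c: [] for c in spec.chrom_lengths
    }
    truth: list[SnpIsland] = []
    guard = spec.max_island_len + spec.min_flank_len
    excluded: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_lengths}

    for isl in sorted(spec.islands, key=lambda i: (i.chrom, i.core_start)):
        positions = _planted_positions(rng, isl, spec.min_flank_len)
        afs = rng.uniform(0.30, 0.70, size=isl.n_impactful)
        members = []
        for pos, af in zip(positions, afs):
            ref = genome.sequence(isl.chrom)[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            members.append(
                AlleleFrequencyRecord(isl.chrom, int(pos), ref, str(alt), float(af))
            )
        records[isl.chrom].extend(members)
        truth.append(
            SnpIsland(
                chrom=isl.chrom,
                core_start=isl.core_start,
                core_end=isl.core_end,
                flank1_start=isl.core_start - spec.min_flank_len,
                flank2_end=isl.core_end + spec.min_flank_len,
                impactful_snps=members,
                other_relevant_snps=[],
            )
        )
        excluded[isl.chrom].append((isl.core_start - guard, isl.core_end + guard))

    for chrom, length in spec.chrom_lengths.items():
        n_bg = rng.poisson(spec.background_density * length)
        taken = {r.pos for r in records[chrom]}
        candidates = rng.integers(1, length + 1, size=3 * n_bg)
        afs = _draw_background_af(rng, len(candidates))
        placed = 0
        for pos, af in zip(candidates, afs):
            if placed >= n_bg:
                break
            pos = int(pos)
            if pos in taken or any(a <= pos <= b for a, b in excluded[chrom]):
                continue
            ref = genome.sequence(chrom)[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            records[chrom].append(
                AlleleFrequencyRecord(chrom, pos, ref, str(alt), float(af))
            )
            taken.add(pos)
            placed += 1
        records[chrom].sort(key=lambda r: r.pos)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out_dir / "genome.fa")
        write_vcf(records, spec.chrom_lengths, out_dir / "variants.vcf")
        write_islands_bed(truth, out_dir / "truth_islands.bed")
    return genome, records, truth


def write_vcf(
    records: dict[str, list[AlleleFrequencyRecord]],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Minimal sites-only VCF 4.2 with AF in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom in chrom_lengths:
            for r in records.get(chrom, []):
                fh.write(
                    f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\t.\t"
                    f"AF={r.af:.6f}\n"
                )


GENOTYPE_CODE = {0: 1, 1: 2, 2: 3}  # alt-allele dosage -> zygosity code
_MU_BY_DOSAGE = {0: None, 1: 0.5, 2: None}  # filled per error rate


def _ref_call_prob(dosage: int, eps: float) -> float:
    return {0: 1.0 - eps, 1: 0.5, 2: eps}[dosage]


def _panel_snps(islands: list[SnpIsland]) -> list[AlleleFrequencyRecord]:
    snps = [r for isl in islands for r in isl.impactful_snps + isl.other_relevant_snps]
    return sorted(snps, key=lambda r: (r.chrom, r.pos))


def simulate_counts(
    spec: SimulationSpec,
    islands: list[SnpIsland],
    n_samples: int,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-contributor read counts over all island SNPs.

    Returns (counts, truth): counts has columns sample/chrom/pos/ref_calls/
    depth, truth has the drawn genotype as a 1/2/3 zygosity code.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    snps = _panel_snps(islands)
    counts_rows = []
    truth_rows = []
    for s in range(n_samples):
        sample = f"S{s + 1:02d}"
        for snp in snps:
            dosage = int(rng.binomial(2, snp.af))
            n = max(1, int(rng.poisson(spec.mean_depth)))
            x = int(rng.binomial(n, _ref_call_prob(dosage, spec.error_rate)))
            counts_rows.append((sample, snp.chrom, snp.pos, x, n))
            truth_rows.append((sample, snp.chrom, snp.pos, GENOTYPE_CODE[dosage]))
    counts = pd.DataFrame(
        counts_rows, columns=["sample", "chrom", "pos", "ref_calls", "depth"]
    )
    truth = pd.DataFrame(truth_rows, columns=["sample", "chrom", "pos", "code"])
    return counts, truth


def simulate_mixture_counts(
    spec: SimulationSpec,
    islands: list[SnpIsland],
    ratio: tuple[float, float] | None = None,
    sample: str = "MIX",
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-contributor mixture: reference-call probability is the
    ratio-weighted average of the contributors' genotype probabilities."""
    w1, w2 = ratio if ratio is not None else spec.mixture_ratio
    total = w1 + w2
    w1, w2 = w1 / total, w2 / total
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    snps = _panel_snps(islands)
    counts_rows = []
    truth_rows = []
    for snp in snps:
        d1 = int(rng.binomial(2, snp.af))
        d2 = int(rng.binomial(2, snp.af))
        mu = w1 * _ref_call_prob(d1, spec.error_rate) + w2 * _ref_call_prob(
            d2, spec.error_rate
        )
        n = max(1, int(rng.poisson(spec.mean_depth)))
        x = int(rng.binomial(n, mu))
        counts_rows.append((sample, snp.chrom, snp.pos, x, n))
        truth_rows.append(
            (sample, snp.chrom, snp.pos, GENOTYPE_CODE[d1], GENOTYPE_CODE[d2])
        )
    counts = pd.DataFrame(
        counts_rows, columns=["sample", "chrom", "pos", "ref_calls", "depth"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "chrom", "pos", "code_1", "code_2"]
    )
    return counts, truth
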