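"""Reference-genome and allele-frequency input, island output.

Coordinates are 1-based closed everywhere inside the package (the VCF
convention); the single conversion to 0-based half-open happens at the BED
boundary in :func:`write_islands_bed`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_SNV_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AlleleFrequencyRecord:
    """One biallelic SNV with its global alternate-allele frequency."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    af: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not (0.0 <= self.af <= 1.0):
            raise ValueError(f"allele frequency must lie in [0, 1], got {self.af}")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError("only single-base alleles are supported")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if self.ref_allele not in _SNV_BASES or self.alt_allele not in _SNV_BASES:
            raise ValueError("alleles must be one of A, C, G, T")


class ReferenceGenome:
    """Uppercase DNA sequences keyed by chromosome name."""

    def __init__(self, sequences: Mapping[str, str]):
        self._sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(f"chromosome {name!r} contains invalid bases: {sorted(bad)}")
            self._sequences[name] = seq

    @property
    def chromosomes(self) -> list[str]:
        return list(self._sequences)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sequences

    def sequence(self, chrom: str) -> str:
        try:
            return self._sequences[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def subsequence(self, chrom: str, start: int, end: int) -> str:
        """Bases from ``start`` to ``end`` inclusive (1-based closed)."""
        seq = self.sequence(chrom)
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(
                f"requested {chrom}:{start}-{end} outside 1..{len(seq)}"
            )
        return seq[start - 1 : end]


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a (plain-text) FASTA file into a :class:`ReferenceGenome`."""
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return ReferenceGenome(records)


def write_fasta(genome: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_allele_frequencies(
    vcf_path: str | Path,
) -> dict[str, list[AlleleFrequencyRecord]]:
    """Read biallelic SNVs with their global AF from a VCF file.

    AF is taken from the INFO field when present; otherwise it is recomputed
    as alternate-allele count over called allele number from the genotype
    columns.  Indels, multi-allelic records and records with neither an AF tag
    nor genotypes are skipped (counted and logged).  Input must be sorted by
    chromosome then position; unsorted input is a hard error.
    """
    from cyvcf2 import VCF

    out: dict[str, list[AlleleFrequencyRecord]] = {}
    n_skipped_nonsnv = 0
    n_skipped_noaf = 0
    seen_chroms: list[str] = []
    last_pos = 0

    vcf = VCF(str(vcf_path))
    try:
        for variant in vcf:
            chrom = variant.CHROM
            if not seen_chroms or chrom != seen_chroms[-1]:
                if chrom in seen_chroms:
                    raise ValueError(
                        f"unsorted VCF: chromosome {chrom!r} appears in two blocks"
                    )
                seen_chroms.append(chrom)
                last_pos = 0
            if variant.POS < last_pos:
                raise ValueError(
                    f"unsorted VCF: {chrom}:{variant.POS} after {chrom}:{last_pos}"
                )
            last_pos = variant.POS

            alts = variant.ALT
            if len(alts) != 1 or len(variant.REF) != 1 or len(alts[0]) != 1:
                n_skipped_nonsnv += 1
                continue
            if variant.REF not in _SNV_BASES or alts[0] not in _SNV_BASES:
                n_skipped_nonsnv += 1
                continue

            af = _extract_af(variant)
            if af is None:
                n_skipped_noaf += 1
                logger.warning(
                    "no AF tag and no genotypes at %s:%d; record skipped",
                    chrom,
                    variant.POS,
                )
                continue
            out.setdefault(chrom, []).append(
                AlleleFrequencyRecord(
                    chrom=chrom,
                    pos=variant.POS,
                    ref_allele=variant.REF,
                    alt_allele=alts[0],
                    af=min(max(af, 0.0), 1.0),
                )
            )
    finally:
        vcf.close()

    if n_skipped_nonsnv or n_skipped_noaf:
        logger.info(
            "skipped %d non-SNV/multi-allelic and %d AF-less records",
            n_skipped_nonsnv,
            n_skipped_noaf,
        )
    return out


def _extract_af(variant) -> float | None:
    af = variant.INFO.get("AF")
    if af is not None:
        if isinstance(af, (tuple, list)):
            af = af[0]
        return float(af)
    # fall back to counting alternate alleles over called alleles
    genotypes = variant.genotypes
    if not genotypes:
        return None
    alt_count = 0
    total = 0
    for gt in genotypes:
        for allele in gt[:-1]:  # last element is the phasing flag
            if allele < 0:  # missing
                continue
            total += 1
            if allele > 0:
                alt_count += 1
    if total == 0:
        return None
    return alt_count / total


# ---------------------------------------------------------------------------
# tabular output


def write_frequency_table(
    records: Iterable[AlleleFrequencyRecord], path: str | Path
) -> None:
    """Write allele-frequency records as a headered TSV (round-trippable)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\taf\n")
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.ref_allele}\t{rec.alt_allele}\t{rec.af:.10g}\n"
            )


def read_frequency_table(path: str | Path) -> list[AlleleFrequencyRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chrom", "pos", "ref", "alt", "af"]:
            raise ValueError(f"unexpected frequency-table header in {path}")
        for line in fh:
            chrom, pos, ref, alt, af = line.rstrip("\n").split("\t")
            records.append(
                AlleleFrequencyRecord(chrom, int(pos), ref, alt, float(af))
            )
    return records


def write_islands_bed(islands: Iterable, path: str | Path) -> None:
    """Write islands as BED6 over the full target window (flank I -> flank II).

    BED is 0-based half-open: a window covering 1-based closed positions
    [flank1_start, flank2_end] becomes start = flank1_start - 1,
    end = flank2_end.  The name column encodes the impactful-SNP count and the
    score column repeats it.
    """
    islands = list(islands)
    starts_seen: dict[str, int] = {}
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for idx, isl in enumerate(islands):
            n_imp = len(isl.impactful_snps)
            prev_end = starts_seen.get(isl.chrom)
            if prev_end is not None and isl.flank1_start - 1 < prev_end:
                logger.info(
                    "island %d overlaps the previous island on %s", idx, isl.chrom
                )
            starts_seen[isl.chrom] = isl.flank2_end
            fh.write(
                f"{isl.chrom}\t{isl.flank1_start - 1}\t{isl.flank2_end}\t"
                f"island_{idx}_snps{n_imp}\t{n_imp}\t+\n"
            )


def write_islands_table(islands: Iterable, path: str | Path) -> None:
    """Full-fidelity island TSV used to chain pipeline stages."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tcore_start\tcore_end\tflank1_start\tflank2_end\t"
            "impactful\tother_relevant\n"
        )
        for isl in islands:
            imp = ";".join(
                f"{r.pos}:{r.ref_allele}:{r.alt_allele}:{r.af:.10g}"
                for r in isl.impactful_snps
            )
            rel = ";".join(
                f"{r.pos}:{r.ref_allele}:{r.alt_allele}:{r.af:.10g}"
                for r in isl.other_relevant_snps
            )
            fh.write(
                f"{isl.chrom}\t{isl.core_start}\t{isl.core_end}\t"
                f"{isl.flank1_start}\t{isl.flank2_end}\t{imp}\t{rel or '.'}\n"
            )


def read_islands_table(path: str | Path) -> list:
    from .scanner import SnpIsland

    def parse_snps(chrom: str, cell: str) -> list[AlleleFrequencyRecord]:
        if cell in (".", ""):
            return []
        out = []
        for item in cell.split(";"):
            pos, ref, alt, af = item.split(":")
            out.append(AlleleFrequencyRecord(chrom, int(pos), ref, alt, float(af)))
        return out

    islands = []
    with open(path) as fh:
        fh.readline()  # header
        for line in fh:
            chrom, cs, ce, f1, f2, imp, rel = line.rstrip("\n").split("\t")
            islands.append(
                SnpIsland(
                    chrom=chrom,
                    core_start=int(cs),
                    core_end=int(ce),
                    flank1_start=int(f1),
                    flank2_end=int(f2),
                    impactful_snps=parse_snps(chrom, imp),
                    other_relevant_snps=parse_snps(chrom, rel),
                )
            )
    return islands
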