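"""Stage wiring: panel design (scan -> sequence filter -> uniqueness filter)
and identity profiling (call -> compare), with a funnel report."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import RunConfig
from .genome_io import ReferenceGenome
from .profiles import (
    DendrogramNode,
    SimilarityMatrix,
    SnpProfile,
    build_profiles,
    cluster,
    distance_matrix,
    similarity_matrix,
)
from .scanner import SnpIsland, categorize_islands, scan_genome
from .sequence_filters import filter_targets
from .uniqueness import feasibility_filter
from .zygosity import call_table, mixture_flag, ZygosityCall, SnpEvidence

logger = logging.getLogger(__name__)


@dataclass
class PanelDesignResult:
    """Funnel of the three design stages, mirroring the published report shape."""

    scanned: list[SnpIsland]
    after_sequence_filter: list[SnpIsland]
    after_uniqueness_filter: list[SnpIsland]
    sequence_rejects: list
    uniqueness_rejects: list

    @property
    def funnel(self) -> dict[str, int]:
        return {
            "scan": len(self.scanned),
            "sequence_filter": len(self.after_sequence_filter),
            "uniqueness_filter": len(self.after_uniqueness_filter),
        }

    @property
    def categories(self) -> dict[str, int]:
        return categorize_islands(self.after_uniqueness_filter)


def design_panel(
    records_by_chrom: dict,
    genome: ReferenceGenome,
    config: RunConfig | None = None,
) -> PanelDesignResult:
    """Run scan -> sequence filter -> uniqueness filter and report the funnel."""
    config = config or RunConfig()
    scanned = scan_genome(records_by_chrom, config.scanner, genome=genome)
    logger.info("scan: %d candidate islands", len(scanned))
    kept_seq, rej_seq = filter_targets(scanned, genome, config.sequence_filter)
    logger.info("sequence filter: %d islands remain", len(kept_seq))
    kept_uni, rej_uni, _ = feasibility_filter(kept_seq, genome, config.uniqueness)
    logger.info("uniqueness filter: %d islands remain", len(kept_uni))
    return PanelDesignResult(scanned, kept_seq, kept_uni, rej_seq, rej_uni)


@dataclass
class ProfilingResult:
    calls: pd.DataFrame
    profiles: list[SnpProfile]
    similarity: SimilarityMatrix
    dendrogram: DendrogramNode | None
    mixture_fractions: dict[str, float | None]
    mixture_flags: dict[str, bool | None]


def profile_samples(
    counts: pd.DataFrame,
    config: RunConfig | None = None,
    mixture_threshold: float = 0.2,
) -> ProfilingResult:
    """Run call -> compare on a counts table covering >= 2 samples."""
    config = config or RunConfig()
    calls = call_table(counts, config.ci)
    profiles = build_profiles(calls)
    sim = similarity_matrix(profiles)
    # distance requires panel columns called in every sample; with many
    # samples and depth-limited homozygote no-calls that set can vanish
    try:
        ids, dist = distance_matrix(profiles)
        tree: DendrogramNode | None = cluster(ids, dist)
    except ValueError as exc:
        logger.warning("clustering unavailable: %s", exc)
        tree = None
    fractions: dict[str, float | None] = {}
    flags: dict[str, bool | None] = {}
    for sample, group in calls.groupby("sample", sort=True):
        zcalls = [
            ZygosityCall(
                SnpEvidence(str(sample), str(r.chrom), int(r.pos),
                            int(r.ref_calls), int(r.depth)),
                r.p,
                None if pd.isna(r.ci_low) else float(r.ci_low),
                None if pd.isna(r.ci_high) else float(r.ci_high),
                str(r.call),
                None if pd.isna(r.code) else int(r.code),
            )
            for r in group.itertuples(index=False)
        ]
        fractions[str(sample)], flags[str(sample)] = mixture_flag(
            zcalls, mixture_threshold
        )
    return ProfilingResult(calls, profiles, sim, tree, fractions, flags)
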