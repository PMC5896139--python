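from __future__ import annotations

import numpy as np
import pytest

from snpislands.config import RunConfig, ScannerConfig
from snpislands.genome_io import AlleleFrequencyRecord


@pytest.fixture
def scanner_config() -> ScannerConfig:
    return ScannerConfig()


@pytest.fixture
def run_config() -> RunConfig:
    return RunConfig()


def make_records(positions_afs, chrom="chr1"):
    """[(pos, af), ...] -> sorted AlleleFrequencyRecord list (A->G SNVs)."""
    return [
        AlleleFrequencyRecord(chrom, pos, "A", "G", af)
        for pos, af in sorted(positions_afs)
    ]


def random_af_landscape(rng: np.random.Generator, length: int, density: float = 0.004):
    """Random sorted records with AFs spanning all scanner classes."""
    n = rng.poisson(density * length)
    positions = np.sort(rng.choice(np.arange(1, length + 1), size=min(n, length), replace=False))
    afs = rng.uniform(0.0, 1.0, size=len(positions))
    # push a fraction into the near-fixed bands so ignorable SNPs occur
    fixed = rng.random(len(positions)) < 0.3
    afs[fixed] = np.where(rng.random(fixed.sum()) < 0.5, 0.001, 0.999)
    return make_records(list(zip(positions.tolist(), afs.tolist())))


def random_sequence(rng: np.random.Generator, length: int, with_n: bool = False) -> str:
    bases = "ACGTN" if with_n else "ACGT"
    p = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    return "".join(rng.choice(list(bases), size=length, p=p))
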