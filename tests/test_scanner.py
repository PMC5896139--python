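"""Three-state island scanner: hand-traced examples, invariants, and
equivalence with the brute-force candidate enumerator."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from conftest import random_af_landscape
from oracles import brute_force_scan

from snpislands.genome_io import AlleleFrequencyRecord
from snpislands.scanner import (
    SnpClass,
    categorize_islands,
    classify_snp,
    scan_chromosome,
)


def rec(pos, af, chrom="chr1"):
    return AlleleFrequencyRecord(chrom, pos, "A", "G", af)


class TestClassify:
    @pytest.mark.parametrize(
        "af,expected",
        [
            (0.50, SnpClass.IMPACTFUL),
            (0.30, SnpClass.IMPACTFUL),  # band bounds are inclusive
            (0.70, SnpClass.IMPACTFUL),
            (0.004, SnpClass.IGNORABLE),
            (0.005, SnpClass.IGNORABLE),  # conserved tolerance is inclusive
            (0.995, SnpClass.IGNORABLE),
            (0.999, SnpClass.IGNORABLE),
            (0.10, SnpClass.RELEVANT),
            (0.299, SnpClass.RELEVANT),
            (0.80, SnpClass.RELEVANT),
        ],
    )
    def test_frequency_bands(self, af, expected, scanner_config):
        assert classify_snp(rec(1000, af), scanner_config) is expected


class TestHandTracedScans:
    def test_no_records_no_islands(self, scanner_config):
        assert scan_chromosome([], 10_000, scanner_config) == []

    def test_three_clustered_impactful_snps_form_one_island(self, scanner_config):
        records = [rec(1000, 0.5), rec(1100, 0.5), rec(1200, 0.5)]
        islands = scan_chromosome(records, 5000, scanner_config)
        assert len(islands) == 1
        isl = islands[0]
        assert (isl.core_start, isl.core_end) == (1000, 1200)
        assert (isl.flank1_start, isl.flank2_end) == (850, 1350)
        assert len(isl.impactful_snps) == 3

    def test_relevant_snps_forcing_core_past_cap_regress(self, scanner_config):
        # relevant SNP at 1300 breaks LV2; absorbing it is fine (301 bp) but
        # the next breaker at 1400 would need a 401 bp core -> no island
        records = [
            rec(1000, 0.5),
            rec(1100, 0.5),
            rec(1200, 0.5),
            rec(1300, 0.10),
            rec(1400, 0.10),
        ]
        assert scan_chromosome(records, 5000, scanner_config) == []

    def test_greedy_extension_absorbs_all_five_snps(self, scanner_config):
        records = [rec(p, 0.5) for p in (1000, 1050, 1100, 1150, 1200)]
        islands = scan_chromosome(records, 5000, scanner_config)
        assert len(islands) == 1
        assert len(islands[0].impactful_snps) == 5
        assert (islands[0].core_start, islands[0].core_end) == (1000, 1200)

    def test_relevant_snp_absorbed_into_core_not_counted(self, scanner_config):
        records = [rec(1000, 0.5), rec(1100, 0.5), rec(1150, 0.10), rec(1200, 0.5)]
        islands = scan_chromosome(records, 5000, scanner_config)
        assert len(islands) == 1
        assert [r.pos for r in islands[0].impactful_snps] == [1000, 1100, 1200]
        assert [r.pos for r in islands[0].other_relevant_snps] == [1150]

    def test_island_needs_room_for_left_flank(self, scanner_config):
        # anchor at 100 cannot host a 150 bp upstream flank
        records = [rec(100, 0.5), rec(150, 0.5), rec(200, 0.5)]
        assert scan_chromosome(records, 5000, scanner_config) == []

    def test_island_needs_room_for_right_flank(self, scanner_config):
        records = [rec(900, 0.5), rec(950, 0.5), rec(1000, 0.5)]
        assert scan_chromosome(records, 1100, scanner_config) == []
        assert len(scan_chromosome(records, 1150, scanner_config)) == 1

    def test_ignorable_snps_are_transparent(self, scanner_config):
        records = [
            rec(950, 0.001),  # inside what must be a clean flank
            rec(1000, 0.5),
            rec(1100, 0.5),
            rec(1200, 0.5),
            rec(1250, 0.999),
        ]
        islands = scan_chromosome(records, 5000, scanner_config)
        assert len(islands) == 1
        assert (islands[0].core_start, islands[0].core_end) == (1000, 1200)

    def test_n_run_blocks_flank(self, scanner_config):
        records = [rec(1000, 0.5), rec(1100, 0.5), rec(1200, 0.5)]
        seq = list("A" * 5000)
        seq[1249] = "N"  # position 1250, inside the would-be right flank
        assert scan_chromosome(records, 5000, scanner_config, "".join(seq)) == []
        seq[1249] = "A"
        seq[299] = "N"  # far away: harmless
        assert len(scan_chromosome(records, 5000, scanner_config, "".join(seq))) == 1

    def test_verified_lv2_serves_as_next_lv1(self, scanner_config):
        records = [rec(p, 0.5) for p in (1000, 1100, 1200)] + [
            rec(p, 0.5) for p in (1360, 1400, 1440)
        ]
        islands = scan_chromosome(records, 5000, scanner_config)
        assert [(i.core_start, i.core_end) for i in islands] == [
            (1000, 1200),
            (1360, 1440),
        ]

    def test_unsorted_records_rejected(self, scanner_config):
        with pytest.raises(ValueError, match="sorted"):
            scan_chromosome([rec(200, 0.5), rec(100, 0.5)], 5000, scanner_config)


class TestInvariantsAndProperties:
    def _assert_island_invariants(self, islands, records, config, chrom_length):
        breaking = [
            r.pos
            for r in records
            if classify_snp(r, config) is not SnpClass.IGNORABLE
        ]
        for isl in islands:
            assert isl.core_length <= config.max_island_len
            assert isl.core_start - isl.flank1_start >= config.min_flank_len
            assert isl.flank2_end - isl.core_end >= config.min_flank_len
            assert len(isl.impactful_snps) >= config.min_impactful
            assert isl.flank1_start >= 1 and isl.flank2_end <= chrom_length
            for pos in breaking:
                in_left = isl.flank1_start <= pos < isl.core_start
                in_right = isl.core_end < pos <= isl.flank2_end
                assert not (in_left or in_right)

    def test_emitted_islands_satisfy_invariants(self, scanner_config):
        rng = np.random.default_rng(11)
        for _ in range(50):
            records = random_af_landscape(rng, 30_000)
            islands = scan_chromosome(records, 30_000, scanner_config)
            self._assert_island_invariants(islands, records, scanner_config, 30_000)

    def test_oracle_equivalence_on_random_landscapes(self, scanner_config):
        rng = np.random.default_rng(7)
        n_with_islands = 0
        for _ in range(150):
            length = int(rng.integers(5_000, 50_000))
            records = random_af_landscape(rng, length, density=0.006)
            got = scan_chromosome(records, length, scanner_config)
            expected = brute_force_scan(records, length, scanner_config)
            assert [
                (
                    i.core_start,
                    i.core_end,
                    tuple(r.pos for r in i.impactful_snps),
                    tuple(r.pos for r in i.other_relevant_snps),
                )
                for i in got
            ] == expected
            n_with_islands += bool(got)
        assert n_with_islands > 10  # the comparison must exercise real islands

    def test_loosening_min_impactful_never_loses_islands(self, scanner_config):
        rng = np.random.default_rng(23)
        loose = dataclasses.replace(scanner_config, min_impactful=3)
        strict = dataclasses.replace(scanner_config, min_impactful=5)
        for _ in range(40):
            records = random_af_landscape(rng, 30_000, density=0.008)
            n_loose = len(scan_chromosome(records, 30_000, loose))
            n_strict = len(scan_chromosome(records, 30_000, strict))
            assert n_loose >= n_strict

    def test_tightening_max_island_len_never_gains_islands(self, scanner_config):
        rng = np.random.default_rng(29)
        wide = dataclasses.replace(scanner_config, max_island_len=400)
        narrow = dataclasses.replace(scanner_config, max_island_len=200)
        for _ in range(40):
            records = random_af_landscape(rng, 30_000, density=0.008)
            assert len(scan_chromosome(records, 30_000, narrow)) <= len(
                scan_chromosome(records, 30_000, wide)
            )

    def test_scan_is_deterministic(self, scanner_config):
        rng = np.random.default_rng(31)
        records = random_af_landscape(rng, 40_000, density=0.008)
        a = scan_chromosome(records, 40_000, scanner_config)
        b = scan_chromosome(records, 40_000, scanner_config)
        assert a == b


class TestCategorize:
    def test_empty(self):
        assert categorize_islands([]) == {"5+": 0, "4": 0, "3": 0}

    def test_counting_and_bucketing(self, scanner_config):
        def isl(k):
            snps = [rec(1000 + 10 * i, 0.5) for i in range(k)]
            from snpislands.scanner import SnpIsland

            return SnpIsland("chr1", 1000, 1000 + 10 * (k - 1), 850,
                             1000 + 10 * (k - 1) + 150, snps, [])

        got = categorize_islands([isl(5), isl(4), isl(3), isl(3), isl(7)])
        assert got == {"5+": 2, "4": 1, "3": 2}
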