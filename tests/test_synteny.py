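"""Collinearity block detection: worked examples, oracle equivalence,
tolerance semantics, and structural invariants."""

import numpy as np
import pytest

from synmap import (
    ToleranceRule,
    ValidationError,
    blocks_overlap_check,
    detect_blocks,
    oracle_segment,
)
from conftest import anchor, map_for, random_instance, sizes_for


def detect(anchors, lg_length=100.0, chrom_length=10_000, tau=0.025):
    lmap = map_for(anchors, lg_length=lg_length)
    return detect_blocks(
        anchors, lmap, sizes_for(chrom_length), ToleranceRule(tau=tau)
    )


def block_ids(blocks):
    return [tuple(a.locus_id for a in b.anchors) for b in blocks]


class TestWorkedExamples:
    def test_minimal_two_anchor_block(self):
        blocks = detect([anchor("A", 0.0, 100), anchor("B", 5.0, 200)])
        (b,) = blocks
        assert b.n_loci == 2 and b.orientation == 1
        assert b.genome_span_bp == (100, 200) and b.map_span_cM == (0.0, 5.0)

    def test_super_threshold_departure_breaks_run(self):
        # |dbp| = 50 >= 2.5% of 1000: the trailing anchor cannot join and
        # is dropped as a singleton
        anchors = [anchor("A", 0, 100), anchor("B", 5, 200), anchor("C", 10, 150)]
        blocks = detect(anchors, chrom_length=1000)
        assert block_ids(blocks) == [("A", "B")]

    def test_tolerance_requires_both_axes(self):
        # bp departure below threshold (50 < 250) but cM departure is not
        # (5 >= 2.5): still broken
        anchors = [anchor("A", 0, 100), anchor("B", 5, 200), anchor("C", 10, 150)]
        blocks = detect(anchors, chrom_length=10_000)
        assert block_ids(blocks) == [("A", "B")]

    def test_sub_threshold_departure_tolerated(self):
        # 0.5 cM < 2.5 and 50 bp < 250: one three-anchor block
        anchors = [anchor("A", 0, 100), anchor("B", 1, 200), anchor("C", 1.5, 150)]
        blocks = detect(anchors, chrom_length=10_000)
        assert block_ids(blocks) == [("A", "B", "C")]
        assert blocks[0].orientation == 1

    def test_chromosome_change_interrupts(self):
        anchors = [
            anchor("A", 0, 100),
            anchor("B", 5, 200),
            anchor("X", 7, 5000, chrom="c2"),
            anchor("C", 10, 300),
            anchor("D", 15, 400),
        ]
        lmap = map_for(anchors)
        sizes = {"sp": sizes_for(chroms=("c1", "c2"))["sp"]}
        blocks = detect_blocks(anchors, lmap, sizes, ToleranceRule())
        assert block_ids(blocks) == [("A", "B"), ("C", "D")]

    def test_zero_recombination_bin_single_block_orientation_zero(self):
        anchors = [anchor(f"L{i}", 3.0, bp) for i, bp in enumerate([900, 100, 500])]
        blocks = detect(anchors)
        (b,) = blocks
        assert b.n_loci == 3 and b.orientation == 0

    def test_descending_block_orientation(self):
        anchors = [anchor("A", 0, 900), anchor("B", 5, 500), anchor("C", 9, 100)]
        (b,) = detect(anchors)
        assert b.orientation == -1

    def test_unknown_linkage_group_rejected(self):
        a = [anchor("A", 0, 100), anchor("B", 5, 200, lg="lgX")]
        lmap = map_for(a[:1])
        with pytest.raises(ValidationError, match="lgX"):
            detect_blocks(a, lmap, sizes_for(), ToleranceRule())

    def test_unknown_chromosome_rejected(self):
        a = [anchor("A", 0, 100, chrom="cZ")]
        with pytest.raises(ValidationError, match="cZ"):
            detect_blocks(a, map_for(a), sizes_for(), ToleranceRule())


class TestOracle:
    def test_refuses_large_instances(self):
        anchors = [anchor(f"L{i:02d}", float(i), 10 * i + 10) for i in range(13)]
        with pytest.raises(ValidationError):
            oracle_segment(anchors, ToleranceRule(), 100.0, 10_000)

    def test_perfect_sequence_is_one_run(self):
        anchors = [anchor(f"L{i}", float(i), 100 * (i + 1)) for i in range(6)]
        runs = oracle_segment(anchors, ToleranceRule(), 100.0, 10_000)
        assert runs == [(0, 5)]

    def test_large_internal_inversion_matches_detector(self):
        # three reversed anchors spanning well over tolerance
        cm_bp = [(0, 100), (2, 900), (4, 9000), (6, 6000), (8, 3000),
                 (10, 9500), (12, 9900)]
        anchors = [anchor(f"L{i}", c, b) for i, (c, b) in enumerate(cm_bp)]
        runs = oracle_segment(anchors, ToleranceRule(), 100.0, 10_000)
        blocks = detect(anchors)
        ordered = sorted(anchors, key=lambda a: (a.cm, a.bp, a.locus_id))
        expected = [
            tuple(ordered[k].locus_id for k in range(i, j + 1))
            for i, j in runs
            if j > i
        ]
        assert 2 <= len(runs) <= 3
        assert block_ids(blocks) == expected

    def test_all_tied_bin_is_one_run(self):
        anchors = [anchor(f"L{i}", 5.0, 100 * (i + 1)) for i in range(5)]
        assert oracle_segment(anchors, ToleranceRule(), 100.0, 10_000) == [(0, 4)]

    def test_equivalence_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(250):
            anchors = random_instance(rng)
            tau = float(rng.choice([0.0, 0.025, 0.1]))
            rule = ToleranceRule(tau=tau)
            runs = oracle_segment(anchors, rule, 100.0, 10_000)
            blocks = detect(anchors, tau=tau)
            ordered = sorted(anchors, key=lambda a: (a.cm, a.bp, a.locus_id))
            expected = [
                tuple(ordered[k].locus_id for k in range(i, j + 1))
                for i, j in runs
                if j > i
            ]
            assert block_ids(blocks) == expected


class TestProperties:
    def test_tau_monotonicity_of_block_count(self):
        rng = np.random.default_rng(5)
        taus = [0.0, 0.01, 0.025, 0.05, 0.1, 0.25]
        for _ in range(60):
            anchors = random_instance(rng, n=int(rng.integers(4, 16)))
            counts = [len(detect(anchors, tau=t)) for t in taus]
            assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_reversal_symmetry_on_tie_free_instances(self):
        rng = np.random.default_rng(6)
        for _ in range(80):
            anchors = random_instance(rng, with_ties=False)
            fwd = detect(anchors)
            refl = [
                anchor(a.locus_id, a.cm, 10_000 - a.bp + 1) for a in anchors
            ]
            rev = detect(refl)
            fwd_k = sorted(
                (frozenset(a.locus_id for a in b.anchors), b.orientation)
                for b in fwd
            )
            rev_k = sorted(
                (frozenset(a.locus_id for a in b.anchors), -b.orientation)
                for b in rev
            )
            assert fwd_k == rev_k

    def test_blocks_are_disjoint_and_coverage_bounded(self):
        rng = np.random.default_rng(8)
        anchors = random_instance(rng, n=12)
        blocks = detect(anchors)
        report = blocks_overlap_check(blocks, anchors)
        assert report.disjoint
        cov = report.coverage_by_species["sp"]
        assert 0.0 <= cov <= 1.0
        n_blocked = sum(b.n_loci for b in blocks)
        assert report.unblocked_by_species["sp"] == len(anchors) - n_blocked

    def test_full_coverage_on_clean_collinear_input(self):
        anchors = [anchor(f"L{i}", float(i), 500 * (i + 1)) for i in range(8)]
        blocks = detect(anchors)
        report = blocks_overlap_check(blocks, anchors)
        assert report.coverage_by_species["sp"] == 1.0
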