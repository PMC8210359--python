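import math

import numpy as np
import pytest

from melrna.io_formats import GenomeAlignment, ReadAlignmentGroup, SineLocus
from melrna.quantify import (
    AlignmentIndex,
    LocusExpression,
    LocusIndex,
    aggregate_family,
    assign_read_to_locus,
    bin_multiplicity,
    classify_standalone,
    count_loci,
    expression_histogram,
    multiplicity_fractions,
    normalize_rpm,
    replicate_correlation,
    standalone_summary,
)


def locus(lid="L1", chrom="chr1", start=1000, end=1180, strand="+",
          subfamily="B1_Mm", family="B1"):
    return SineLocus(lid, chrom, start, end, strand, subfamily, family)


def galn(read_id="r1", chrom="chr1", start=1002, end=1130, strand="+"):
    return GenomeAlignment(read_id, chrom, start, end, strand)


def group(read_id, alignments):
    return ReadAlignmentGroup(read_id, alignments)


class TestBinMultiplicity:
    def test_partition_by_enumeration(self):
        """Every count 0..200 lands in exactly one bin, boundaries as printed."""
        expected_edges = {0: "unmapped", 1: "unique", 2: "multi_2_9",
                          9: "multi_2_9", 10: "multi_10_99", 99: "multi_10_99",
                          100: "multi_100_plus"}
        for n in range(201):
            b = bin_multiplicity(n)
            assert b in ("unmapped", "unique", "multi_2_9", "multi_10_99",
                         "multi_100_plus")
            if n in expected_edges:
                assert b == expected_edges[n]

    def test_group_bin(self):
        g = group("r1", [galn(start=i * 10 + 1, end=i * 10 + 5) for i in range(12)])
        assert g.multiplicity_bin == "multi_10_99"
        assert bin_multiplicity(g) == "multi_10_99"

    def test_fractions_sum_to_one(self):
        groups = [group(f"r{i}", [galn()] * (i % 3)) for i in range(30)]
        fracs = multiplicity_fractions(groups)
        assert sum(fracs.values()) == pytest.approx(1.0)


class TestAssignment:
    def test_containment(self):
        index = LocusIndex([locus()])
        assert assign_read_to_locus(galn(start=1002), index) == "L1"

    def test_upstream_slack(self):
        index = LocusIndex([locus()], max_tss_offset=5)
        assert assign_read_to_locus(galn(start=998, end=1100), index) == "L1"
        assert assign_read_to_locus(galn(start=994, end=1100), index) is None

    def test_strand_mismatch(self):
        index = LocusIndex([locus(strand="+")])
        assert assign_read_to_locus(
            galn(start=1050, end=1180, strand="-"), index
        ) is None

    def test_minus_strand_five_prime_end(self):
        index = LocusIndex([locus(strand="-")])
        # minus-strand read 5' end is end-1; allow slack past the locus end
        assert assign_read_to_locus(
            galn(start=1050, end=1183, strand="-"), index
        ) == "L1"

    def test_nested_tie_prefers_nearest_then_smaller(self):
        outer = locus("outer", start=1000, end=1400)
        inner = locus("inner", start=1010, end=1200)
        index = LocusIndex([outer, inner])
        # 5' end at 1010: distance 10 to outer, 0 to inner
        assert assign_read_to_locus(galn(start=1010, end=1100), index) == "inner"
        # equidistant at 1005: smaller locus wins
        equidistant = LocusIndex(
            [locus("big", start=1000, end=1400), locus("small", start=1010, end=1100)]
        )
        assert assign_read_to_locus(galn(start=1005, end=1050), equidistant) == "small"


class TestCountLoci:
    def test_unique_reads_counted_multi_excluded(self):
        index = LocusIndex([locus()])
        groups = [
            group("u1", [galn("u1")]),
            group("u2", [galn("u2")]),
            group("u3", [galn("u3")]),
            group("m1", [galn("m1"), galn("m1", chrom="chr1", start=5000, end=5100)]),
            group("far", [galn("far", start=9000, end=9100)]),
        ]
        exprs, assignments = count_loci(groups, index)
        assert {e.locus_id: e.raw_count for e in exprs} == {"L1": 3}
        # conservation: assigned + unassigned = unique reads
        assert len(assignments) == 4
        assert sum(1 for v in assignments.values() if v is None) == 1

    def test_zero_count_loci_retained(self):
        index = LocusIndex([locus(), locus("L2", start=5000, end=5100)])
        exprs, _ = count_loci([group("u1", [galn("u1")])], index)
        assert {e.locus_id: e.raw_count for e in exprs} == {"L1": 1, "L2": 0}

    def test_restrict_to(self):
        index = LocusIndex([locus()])
        groups = [group("a", [galn("a")]), group("b", [galn("b")])]
        exprs, _ = count_loci(groups, index, restrict_to={"a"})
        assert exprs[0].raw_count == 1


class TestNormalizeRpm:
    def test_definition(self):
        exprs = [LocusExpression(locus(), raw_count=50)]
        normalize_rpm(exprs, 1_000_000)
        assert exprs[0].rpm == pytest.approx(50.0)

    def test_zero_raw_count(self):
        exprs = normalize_rpm([LocusExpression(locus(), raw_count=0)], 100)
        assert exprs[0].rpm == 0.0

    def test_scale_invariance(self):
        e1 = normalize_rpm([LocusExpression(locus(), raw_count=7)], 300)
        e2 = normalize_rpm([LocusExpression(locus(), raw_count=14)], 600)
        assert e1[0].rpm == pytest.approx(e2[0].rpm)

    def test_zero_control_is_an_error(self):
        with pytest.raises(ValueError, match="5S"):
            normalize_rpm([LocusExpression(locus(), raw_count=1)], 0)


class TestAggregateFamily:
    def test_additivity_and_conservation(self):
        exprs = [
            LocusExpression(locus("a"), raw_count=2, rpm=10.0),
            LocusExpression(locus("b"), raw_count=1, rpm=5.0),
            LocusExpression(locus("c", family="B2", subfamily="B2_Mm2"),
                            raw_count=4, rpm=20.0),
        ]
        table = aggregate_family(exprs)
        assert table.loc["B1", "rpm"] == pytest.approx(15.0)
        assert table["raw_count"].sum() == sum(e.raw_count for e in exprs)

    def test_empty(self):
        assert len(aggregate_family([])) == 0


class TestStandalone:
    def _locus(self):
        return locus(start=20_000, end=20_180)

    def test_no_flank_reads_standalone(self):
        call = classify_standalone(self._locus(), AlignmentIndex([]))
        assert call.is_standalone

    def test_same_strand_within_flank_breaks_standalone(self):
        flank = AlignmentIndex([galn("f", start=16_200, end=16_300)])  # 4 kb upstream
        call = classify_standalone(self._locus(), flank)
        assert not call.is_standalone
        assert call.n_flank_reads_same_strand == 1

    def test_opposite_strand_ignored(self):
        flank = AlignmentIndex([galn("f", start=19_000, end=19_100, strand="-")])
        assert classify_standalone(self._locus(), flank).is_standalone

    def test_beyond_flank_ignored(self):
        flank = AlignmentIndex([galn("f", start=26_000, end=26_100)])
        assert classify_standalone(self._locus(), flank, flank_bp=5000).is_standalone

    def test_reads_assigned_to_locus_excluded(self):
        # an alignment straddling the locus start also overlaps the flank
        flank = AlignmentIndex([galn("own", start=19_990, end=20_100)])
        call = classify_standalone(self._locus(), flank, exclude_read_ids={"own"})
        assert call.is_standalone

    def test_strand_flip_flips_verdicts(self):
        flank_alns = [galn("f", start=18_000, end=18_100, strand="+")]
        same = classify_standalone(self._locus(), AlignmentIndex(flank_alns))
        flipped = [GenomeAlignment("f", "chr1", 18_000, 18_100, "-")]
        opp = classify_standalone(self._locus(), AlignmentIndex(flipped))
        assert not same.is_standalone and opp.is_standalone

    def test_summary(self):
        calls = [
            classify_standalone(self._locus(), AlignmentIndex([])),
            classify_standalone(
                self._locus(), AlignmentIndex([galn("f", start=19_000, end=19_100)])
            ),
        ]
        summary = standalone_summary(calls)
        assert summary["n"] == 2
        assert summary["fraction_standalone"] == pytest.approx(0.5)


class TestReplicateCorrelation:
    def _exprs(self, rpms, counts=None):
        counts = counts or [1] * len(rpms)
        return [
            LocusExpression(locus(f"L{i}", start=i * 1000 + 1, end=i * 1000 + 100),
                            raw_count=c, rpm=r)
            for i, (r, c) in enumerate(zip(rpms, counts))
        ]

    def test_identical_replicates(self):
        e = self._exprs([1.0, 5.0, 9.0])
        assert replicate_correlation(e, e) == pytest.approx(1.0)

    def test_scaled_replicate(self):
        e1 = self._exprs([1.0, 5.0, 9.0])
        e2 = self._exprs([2.0, 10.0, 18.0])
        assert replicate_correlation(e1, e2) == pytest.approx(1.0)

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.random(200) * 100
        y = rng.random(200) * 100
        e1, e2 = self._exprs(x), self._exprs(y)
        r = replicate_correlation(e1, e2)
        oracle = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)
        assert abs(r) < 0.2  # independent tables: small correlation

    def test_undefined_cases(self):
        assert math.isnan(replicate_correlation(self._exprs([1.0]), self._exprs([2.0])))
        e_flat = self._exprs([3.0, 3.0, 3.0])
        assert math.isnan(replicate_correlation(e_flat, e_flat))

    def test_different_universes_rejected(self):
        with pytest.raises(ValueError):
            replicate_correlation(self._exprs([1.0, 2.0]), self._exprs([1.0]))


class TestExpressionHistogram:
    def _exprs(self, pairs):
        return [
            LocusExpression(locus(f"L{i}", start=i * 1000 + 1, end=i * 1000 + 100),
                            raw_count=c, rpm=r)
            for i, (c, r) in enumerate(pairs)
        ]

    def test_all_zero(self):
        hist = expression_histogram(self._exprs([(0, 0.0)] * 5))
        assert hist["n_zero"] == 5
        assert hist["counts"].sum() == 0

    def test_single_locus_bin_placement(self):
        hist = expression_histogram(self._exprs([(1, 16.0)]), bin_width=1.0)
        centers = hist["bin_edges"][:-1]
        assert hist["counts"].sum() == 1
        assert centers[np.argmax(hist["counts"])] == pytest.approx(4.0)

    def test_counts_conserve_loci(self):
        pairs = [(0, 0.0)] * 3 + [(i, float(2 ** i)) for i in range(1, 8)]
        hist = expression_histogram(self._exprs(pairs))
        assert hist["n_zero"] + hist["counts"].sum() == len(pairs)
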