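"""Alignment filtering, depth conservation and activity normalization."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilvirome import activity
from soilvirome.io_formats import AlignmentRecord, GeneInterval


def _rec(cigar, nm, start=0, read_length=None, contig="c"):
    rl = read_length or sum(n for op, n in cigar if op in "MIS=X")
    return AlignmentRecord("r", contig, start, tuple(cigar), rl, nm)


class TestMetrics:
    def test_full_match_with_two_edits(self):
        identity, frac = activity.alignment_metrics(_rec([("M", 100)], 2))
        assert identity == pytest.approx(0.98)
        assert frac == pytest.approx(1.0)

    def test_soft_clip_halves_fraction(self):
        identity, frac = activity.alignment_metrics(
            _rec([("M", 50), ("S", 50)], 0))
        assert frac == pytest.approx(0.5)
        assert identity == pytest.approx(1.0)

    def test_missing_nm_refused(self):
        with pytest.raises(ValueError, match="NM"):
            activity.alignment_metrics(_rec([("M", 100)], None))


class TestFilter:
    def test_strict_boundaries(self):
        """Records at exactly identity 0.95 or fraction 0.80 are rejected."""
        at_identity = _rec([("M", 100)], 5)            # identity = 0.95
        at_fraction = _rec([("M", 80), ("S", 20)], 0)  # fraction = 0.80
        good = _rec([("M", 100)], 2)
        out = activity.filter_alignments([at_identity, at_fraction, good])
        assert list(out) == [good]
        assert out.rejected == {"low_identity": 1, "low_fraction": 1}

    def test_missing_nm_counted(self):
        out = activity.filter_alignments([_rec([("M", 100)], None)])
        assert list(out) == [] and out.rejected["missing_nm"] == 1

    def test_empty_input(self):
        assert list(activity.filter_alignments([])) == []


class TestDepth:
    def test_two_half_spans_give_unit_coverage(self):
        recs = [_rec([("M", 50)], 0, start=0), _rec([("M", 50)], 0, start=50)]
        prof = activity.depth_and_activity(recs, "c", 100, 10 ** 6)
        assert prof.average_base_coverage == pytest.approx(1.0)
        assert prof.depth.sum() == 100

    def test_no_reads_zero_activity(self):
        prof = activity.depth_and_activity([], "c", 100, 10 ** 6)
        assert prof.normalized_activity == 0.0

    def test_doubling_totals_halves_activity(self):
        recs = [_rec([("M", 50)], 0)]
        a1 = activity.depth_and_activity(recs, "c", 100, 10 ** 6)
        a2 = activity.depth_and_activity(recs, "c", 100, 2 * 10 ** 6)
        assert a2.normalized_activity == pytest.approx(
            a1.normalized_activity / 2)

    def test_duplication_with_doubled_totals_is_invariant(self):
        recs = [_rec([("M", 50)], 0), _rec([("M", 30)], 1, start=10)]
        a1 = activity.depth_and_activity(recs, "c", 100, 1000)
        a2 = activity.depth_and_activity(recs * 2, "c", 100, 2000)
        assert a2.normalized_activity == pytest.approx(a1.normalized_activity)

    def test_deletion_consumes_reference_depth(self):
        prof = activity.depth_and_activity(
            [_rec([("M", 10), ("D", 2), ("M", 10)], 2)], "c", 50, 10 ** 6)
        assert prof.depth.sum() == 22

    def test_zero_length_contig_rejected(self):
        with pytest.raises(ValueError):
            activity.depth_and_activity([], "c", 0, 100)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 400), st.integers(1, 80),
                  st.integers(0, 10), st.integers(0, 10)),
        min_size=0, max_size=12))
    def test_depth_conservation_fuzz(self, specs):
        """sum(depth) equals total aligned reference bases, exactly."""
        recs = []
        expected = 0
        for start, m, d, s in specs:
            start = min(start, 500 - (m + d))
            recs.append(_rec([("M", m), ("D", d), ("S", s)], 0, start=start))
            expected += m + d
        prof = activity.depth_and_activity(recs, "c", 500, 10 ** 6)
        assert int(prof.depth.sum()) == expected


class TestPartition:
    GENES = [GeneInterval(10, 50, "+", "g1")]

    def test_inside_gene_is_coding(self):
        c, nc, _ = activity.partition_coding(
            [_rec([("M", 20)], 0, start=15)], self.GENES, 100)
        assert (c, nc) == (1, 0)

    def test_intergenic_is_noncoding(self):
        c, nc, pct = activity.partition_coding(
            [_rec([("M", 20)], 0, start=60)], self.GENES, 100)
        assert (c, nc) == (0, 1) and pct == 100.0

    def test_exact_tie_counts_as_coding(self):
        c, nc, _ = activity.partition_coding(
            [_rec([("M", 20)], 0, start=40)], self.GENES, 100)
        assert (c, nc) == (1, 0)

    def test_counts_sum_to_retained(self, rng):
        recs = [_rec([("M", 25)], 0, start=int(rng.integers(0, 75)))
                for _ in range(50)]
        c, nc, _ = activity.partition_coding(recs, self.GENES, 100)
        assert c + nc == 50


class TestMarkers:
    CLASSES = {"int_1": "integrase", "exc_1": "excisionase"}

    def test_no_hits_zero_for_both(self):
        counts = activity.marker_counts([], self.CLASSES, 10 ** 6)
        assert counts == {"excisionase": 0.0, "integrase": 0.0}

    def test_per_million_arithmetic(self):
        recs = [_rec([("M", 100)], 0, contig="int_1") for _ in range(20)]
        counts = activity.marker_counts(recs, self.CLASSES, 10 ** 6)
        assert counts["integrase"] == pytest.approx(20.0)

    def test_filter_applied_before_counting(self):
        bad = _rec([("M", 100)], 10, contig="int_1")   # identity 0.90
        counts = activity.marker_counts([bad], self.CLASSES, 10 ** 6)
        assert counts["integrase"] == 0.0
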