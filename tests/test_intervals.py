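"""Interval algebra and format I/O."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epistate import (
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    ParseError,
    bin_occupancy,
    closest_tss_distance,
    coverage_fraction,
    promoter_window,
    read_intervals,
    read_peak_records,
    write_intervals,
)

from _oracles import (
    bool_mask,
    brute_bin_fractions,
    brute_closest_tss,
    brute_coverage_fraction,
    random_interval_set,
)


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "chrom,start,end",
        [("", 0, 10), ("chr1", -1, 10), ("chr1", 10, 10), ("chr1", 10, 5)],
    )
    def test_invalid_coordinates_rejected(self, chrom, start, end):
        with pytest.raises(ValueError):
            GenomicInterval(chrom, start, end)

    def test_width(self):
        assert GenomicInterval("chr1", 3, 10).width == 7


class TestIntervalSetNormalization:
    def test_overlapping_records_merge_to_union(self):
        s = IntervalSet([("chr1", 0, 100), ("chr1", 50, 150)])
        assert list(s.intervals()) == [GenomicInterval("chr1", 0, 150)]
        assert s.total_bp == 150

    def test_bookended_records_merge(self):
        s = IntervalSet([("chr1", 0, 5), ("chr1", 5, 10)])
        assert s.total_bp == 10 and len(s) == 1

    def test_total_bp_order_invariant(self, rng):
        ivs = [("chr1", int(a), int(a + b)) for a, b in
               zip(rng.integers(0, 1000, 30), rng.integers(1, 50, 30))]
        s1 = IntervalSet(ivs)
        s2 = IntervalSet(reversed(ivs))
        assert s1 == s2 and s1.total_bp == s2.total_bp

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)),
            min_size=1,
            max_size=25,
        )
    )
    def test_normalization_idempotent(self, raw):
        s = IntervalSet([("chr1", a, a + w) for a, w in raw])
        again = IntervalSet((iv.chrom, iv.start, iv.end) for iv in s.intervals())
        assert s == again

    def test_subtract_then_union_restores_superset(self, rng):
        a = random_interval_set(rng)
        b = random_interval_set(rng)
        restored = a.subtract(b).union(a.intersect(b))
        assert restored == a


class TestSetAlgebraAgainstPerBaseOracle:
    def test_intersect_subtract_union(self, rng):
        L = 100_000
        for _ in range(10):
            a = random_interval_set(rng, length=L)
            b = random_interval_set(rng, length=L)
            ma, mb = bool_mask(a, "chrT", L), bool_mask(b, "chrT", L)
            assert bool_mask(a.intersect(b), "chrT", L).tolist() == (ma & mb).tolist()
            assert bool_mask(a.subtract(b), "chrT", L).tolist() == (ma & ~mb).tolist()
            assert bool_mask(a.union(b), "chrT", L).tolist() == (ma | mb).tolist()

    def test_overlap_bp_matches_mask(self, rng):
        L = 100_000
        a = random_interval_set(rng, length=L)
        mask = bool_mask(a, "chrT", L)
        qs = rng.integers(0, L - 1, size=200)
        qe = np.minimum(qs + rng.integers(1, 5000, size=200), L)
        got = a.overlap_bp("chrT", qs, qe)
        expected = [mask[s:e].sum() for s, e in zip(qs, qe)]
        assert got.tolist() == expected


class TestCoverageFraction:
    def test_half_overlap(self):
        a = IntervalSet([("chr1", 0, 100)])
        b = IntervalSet([("chr1", 50, 150)])
        assert coverage_fraction(a, b) == 0.5

    def test_full_cover(self):
        a = IntervalSet([("chr1", 0, 100), ("chr1", 200, 300)])
        b = IntervalSet([("chr1", 0, 300)])
        assert coverage_fraction(a, b) == 1.0

    def test_empty_anchor_is_error(self):
        with pytest.raises(ValueError):
            coverage_fraction(IntervalSet(), IntervalSet([("chr1", 0, 10)]))

    def test_shared_overlap_symmetry(self, rng):
        # fraction(a,b) * |a| == fraction(b,a) * |b| (same overlap bp)
        for _ in range(20):
            a = random_interval_set(rng)
            b = random_interval_set(rng)
            lhs = coverage_fraction(a, b) * a.total_bp
            rhs = coverage_fraction(b, a) * b.total_bp
            assert lhs == pytest.approx(rhs)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(20):
            a = random_interval_set(rng)
            b = random_interval_set(rng)
            assert coverage_fraction(a, b) == pytest.approx(
                brute_coverage_fraction(a, b, "chrT", 100_000)
            )


class TestPromoterWindow:
    def test_plus_strand_symmetric(self):
        g = GeneModel("g", "chr1", "+", 10_000)
        w = promoter_window(g, 2000, 2000, GenomeLayout({"chr1": 100_000}))
        assert (w.start, w.end) == (8000, 12_000)

    def test_minus_strand_flips_asymmetric_window(self):
        g = GeneModel("g", "chr1", "-", 10_000)
        w = promoter_window(g, 2000, 300, GenomeLayout({"chr1": 100_000}))
        assert (w.start, w.end) == (9700, 12_000)

    def test_left_clipping(self):
        g = GeneModel("g", "chr1", "+", 500)
        w = promoter_window(g, 2000, 2000, GenomeLayout({"chr1": 100_000}))
        assert (w.start, w.end) == (0, 2500)

    def test_window_outside_chromosome_is_error(self):
        g = GeneModel("g", "chr1", "+", 99_000)
        with pytest.raises(ValueError):
            promoter_window(g, 2000, 2000, GenomeLayout({"chr1": 90_000}))


class TestClosestTssDistance:
    def test_containment_and_gap(self):
        peaks = IntervalSet([("chr1", 100, 200)])
        assert closest_tss_distance(peaks, [GeneModel("a", "chr1", "+", 150)]) == [0]
        assert closest_tss_distance(peaks, [GeneModel("a", "chr1", "+", 500)]) == [300]

    def test_bookended_touch_is_zero(self):
        peaks = IntervalSet([("chr1", 100, 200)])
        assert closest_tss_distance(peaks, [GeneModel("a", "chr1", "+", 200)]) == [0]

    def test_chromosome_without_tss_flagged_missing(self):
        peaks = IntervalSet([("chr2", 0, 10)])
        assert closest_tss_distance(peaks, [GeneModel("a", "chr1", "+", 5)]) == [None]

    def test_matches_all_pairs_enumeration(self, rng):
        peaks = random_interval_set(rng, n=50)
        genes = [
            GeneModel(f"g{i}", "chrT", "+", int(p))
            for i, p in enumerate(rng.integers(0, 100_000, size=20))
        ]
        assert closest_tss_distance(peaks, genes) == brute_closest_tss(peaks, genes)


class TestBinOccupancy:
    def test_half_and_full_bins(self):
        layout = GenomeLayout({"chr1": 1500})
        frac = bin_occupancy(IntervalSet([("chr1", 0, 250)]), layout, 500)["chr1"]
        assert frac.tolist() == [0.5, 0.0, 0.0]
        frac = bin_occupancy(IntervalSet([("chr1", 500, 1000)]), layout, 500)["chr1"]
        assert frac.tolist() == [0.0, 1.0, 0.0]

    def test_short_last_bin_normalized_by_actual_width(self):
        layout = GenomeLayout({"chr1": 1200})
        frac = bin_occupancy(IntervalSet([("chr1", 1000, 1200)]), layout, 500)["chr1"]
        assert frac.tolist() == [0.0, 0.0, 1.0]

    def test_matches_per_base_oracle_and_conserves_bp(self, rng):
        L = 100_000
        layout = GenomeLayout({"chrT": L})
        for _ in range(10):
            peaks = random_interval_set(rng, length=L)
            frac = bin_occupancy(peaks, layout, 500)["chrT"]
            np.testing.assert_allclose(
                frac, brute_bin_fractions(peaks, "chrT", L, 500)
            )
            widths = np.full(len(frac), 500.0)
            widths[-1] = L - 500 * (len(frac) - 1)
            assert (frac * widths).sum() == pytest.approx(peaks.total_bp)


class TestReaders:
    def test_bed_line_maps_directly(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        s = read_intervals(p)
        assert list(s.intervals()) == [GenomicInterval("chr1", 0, 100)]

    def test_track_and_comment_lines_skipped(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\n# c\nchr1\t5\t10\n")
        assert read_intervals(p).total_bp == 5

    @pytest.mark.parametrize(
        "line", ["chr1\tx\t100", "chr1\t100\t50", "chr1\t100"]
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t10\n" + line + "\n")
        with pytest.raises(ParseError, match="line 2"):
            read_intervals(p)

    def test_narrowpeak_requires_ten_columns(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t0\t100\tpk\t5\n")
        with pytest.raises(ParseError, match="10 columns"):
            read_peak_records(p, fmt="narrowPeak")

    def test_unknown_format_is_usage_error(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t1\n")
        with pytest.raises(ValueError, match="unknown format"):
            read_intervals(p, fmt="gff")

    def test_write_read_round_trip_of_random_records(self, tmp_path, rng):
        ivs = [
            ("chr%d" % rng.integers(1, 4), int(s), int(s + w))
            for s, w in zip(
                rng.integers(0, 50_000, 200), rng.integers(1, 2000, 200)
            )
        ]
        original = IntervalSet(ivs)
        p = tmp_path / "rt.bed"
        write_intervals(original, p)
        assert read_intervals(p) == original
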