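"""Weighted region methylation, shores and gradients, Bismark I/O."""
import numpy as np
import pandas as pd
import pytest

from epistate import (
    CGIAnnotation,
    CpGCall,
    GeneModel,
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    derive_shores,
    promoter_methylation_table,
    read_bismark_coverage,
    region_methylation,
    shore_gradient,
    write_bismark_coverage,
)

from _oracles import bool_mask, mask_to_intervals, random_interval_set


REGION = GenomicInterval("chr1", 0, 1000)


class TestRegionMethylation:
    def test_equal_weights(self):
        calls = [CpGCall("chr1", 1, 1.0, 10), CpGCall("chr1", 2, 0.0, 10)]
        assert region_methylation(calls, REGION) == pytest.approx(0.5)

    def test_unequal_weights(self):
        calls = [CpGCall("chr1", 1, 1.0, 30), CpGCall("chr1", 2, 0.5, 10)]
        assert region_methylation(calls, REGION) == pytest.approx(0.875)

    def test_min_coverage_filter_drops_low_cpgs(self):
        calls = [CpGCall("chr1", 1, 1.0, 2)]
        assert np.isnan(region_methylation(calls, REGION, min_cov=3))
        assert region_methylation(calls, REGION, min_cov=2) == 1.0

    def test_per_region_total_mode(self):
        calls = [CpGCall("chr1", 1, 1.0, 2), CpGCall("chr1", 2, 0.0, 2)]
        # per-CpG: nothing passes; per-region total (4 >= 3): defined
        assert np.isnan(region_methylation(calls, REGION, min_cov=3))
        assert region_methylation(
            calls, REGION, min_cov=3, per_region_total=True
        ) == pytest.approx(0.5)

    def test_equal_coverage_reduces_to_unweighted_mean(self, rng):
        fr = rng.random(20)
        calls = [CpGCall("chr1", i, float(f), 7) for i, f in enumerate(fr)]
        assert region_methylation(calls, REGION, min_cov=0) == pytest.approx(fr.mean())

    def test_split_and_pool_invariance(self, rng):
        calls = [
            CpGCall("chr1", int(p), float(f), int(c))
            for p, f, c in zip(
                rng.integers(0, 1000, 40), rng.random(40), rng.integers(3, 40, 40)
            )
        ]
        whole = region_methylation(calls, REGION)
        left = GenomicInterval("chr1", 0, 500)
        right = GenomicInterval("chr1", 500, 1000)
        df = pd.DataFrame(
            [(c.chrom, c.pos, c.fraction, c.coverage) for c in calls],
            columns=["chrom", "pos", "fraction", "coverage"],
        )
        num = den = 0.0
        for reg in (left, right):
            sub = df[(df.pos >= reg.start) & (df.pos < reg.end)]
            num += (sub.fraction * sub.coverage).sum()
            den += sub.coverage.sum()
        assert whole == pytest.approx(num / den)

    def test_raising_min_cov_never_recovers_regions(self, rng):
        calls = [
            CpGCall("chr1", int(p), float(f), int(c))
            for p, f, c in zip(
                rng.integers(0, 5000, 50), rng.random(50), rng.integers(0, 10, 50)
            )
        ]
        regions = [GenomicInterval("chr1", i * 500, (i + 1) * 500) for i in range(10)]
        defined = [
            sum(not np.isnan(region_methylation(calls, r, min_cov=mc)) for r in regions)
            for mc in (0, 2, 4, 8)
        ]
        assert defined == sorted(defined, reverse=True)


class TestPromoterMethylationTable:
    def test_constant_rows(self):
        layout = GenomeLayout({"chr1": 100_000})
        genes = [GeneModel("g1", "chr1", "+", 10_000)]
        zero = [CpGCall("chr1", 9_500, 0.0, 10)]
        one = [CpGCall("chr1", 9_500, 1.0, 10)]
        table = promoter_methylation_table({"a": zero, "b": one}, genes, layout)
        assert table.loc["a", "g1"] == 0.0 and table.loc["b", "g1"] == 1.0

    def test_every_cell_matches_direct_recompute(self, rng):
        layout = GenomeLayout({"chr1": 100_000})
        genes = [
            GeneModel(f"g{i}", "chr1", "+-"[i % 2], 10_000 + 20_000 * i)
            for i in range(4)
        ]
        samples = {}
        for s in ("x", "y"):
            samples[s] = [
                CpGCall("chr1", int(p), float(f), int(c))
                for p, f, c in zip(
                    rng.integers(0, 100_000, 400),
                    rng.random(400),
                    rng.integers(0, 30, 400),
                )
            ]
        table = promoter_methylation_table(samples, genes, layout, min_cov=3)
        from epistate.intervals import promoter_window

        for s in samples:
            for g in genes:
                w = promoter_window(g, 2000, 2000, layout)
                expected = region_methylation(samples[s], w, min_cov=3)
                got = table.loc[s, g.gene_id]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)


class TestShores:
    def test_flank_construction(self):
        layout = GenomeLayout({"chr1": 100_000})
        islands = IntervalSet([("chr1", 10_000, 11_000)])
        ann = derive_shores(islands, layout, shore_bp=2000)
        assert list(
            (iv.start, iv.end) for iv in ann.shores.intervals()
        ) == [(8000, 10_000), (11_000, 13_000)]

    def test_inter_island_gap_fully_shore_without_island_overlap(self):
        layout = GenomeLayout({"chr1": 100_000})
        islands = IntervalSet([("chr1", 10_000, 11_000), ("chr1", 12_000, 13_000)])
        ann = derive_shores(islands, layout, shore_bp=2000)
        gap = ann.shores.intersect(IntervalSet([("chr1", 11_000, 12_000)]))
        assert gap.total_bp == 1000
        assert ann.shores.intersect(islands).total_bp == 0

    def test_shores_disjoint_from_islands_per_base(self, rng):
        layout = GenomeLayout({"chrT": 100_000})
        for _ in range(10):
            islands = random_interval_set(rng, n=10, max_len=2000)
            ann = derive_shores(islands, layout, shore_bp=1500)
            mi = bool_mask(islands, "chrT", 100_000)
            ms = bool_mask(ann.shores, "chrT", 100_000)
            assert not (mi & ms).any()
            # shores equal dilation minus islands
            grown = bool_mask(islands.expand(1500, layout), "chrT", 100_000)
            assert mask_to_intervals(grown & ~mi, "chrT") == ann.shores


class TestShoreGradient:
    def _annotation(self):
        layout = GenomeLayout({"chr1": 100_000})
        islands = IntervalSet([("chr1", 20_000, 21_000)])
        return derive_shores(islands, layout, shore_bp=2000)

    def test_uniform_methylation_flat_gradient(self):
        ann = self._annotation()
        calls = [
            CpGCall("chr1", p, 0.8, 10)
            for p in range(18_000, 23_000, 97)
        ]
        grad = shore_gradient(calls, ann, bin_bp=500)
        assert np.allclose(grad["mean_methylation"], 0.8)

    def test_single_cpg_binning_arithmetic(self):
        ann = self._annotation()
        calls = [CpGCall("chr1", 21_000 + 150 - 1, 0.4, 10)]  # distance 150
        grad = shore_gradient(calls, ann, bin_bp=100)
        assert len(grad) == 1
        assert (grad.loc[0, "bin_start"], grad.loc[0, "bin_end"]) == (100, 200)

    def test_planted_linear_ramp_recovered_monotone(self):
        ann = self._annotation()
        calls = []
        for p in range(18_000, 20_000, 37):
            d = 20_000 - p
            calls.append(CpGCall("chr1", p, 0.1 + 0.8 * d / 2000, 20))
        for p in range(21_000, 23_000, 37):
            d = p - 21_000 + 1
            calls.append(CpGCall("chr1", p, 0.1 + 0.8 * d / 2000, 20))
        grad = shore_gradient(calls, ann, bin_bp=250)
        assert grad["mean_methylation"].is_monotonic_increasing

    def test_no_shore_cpgs_gives_empty_gradient(self):
        ann = self._annotation()
        grad = shore_gradient([CpGCall("chr1", 50, 0.5, 10)], ann)
        assert grad.empty


class TestBismarkIO:
    def test_one_based_conversion_and_derived_fields(self, tmp_path):
        p = tmp_path / "x.cov"
        p.write_text("chr1\t101\t101\t75\t3\t1\n")
        df = read_bismark_coverage(p)
        assert df.loc[0, "pos"] == 100
        assert df.loc[0, "coverage"] == 4
        assert df.loc[0, "fraction"] == pytest.approx(0.75)

    def test_write_read_round_trip(self, tmp_path, rng):
        cov = rng.integers(1, 40, 50)
        n_meth = rng.binomial(cov, 0.3)
        calls = pd.DataFrame(
            {
                "chrom": "chr2",
                "pos": np.arange(50) * 13,
                "fraction": n_meth / cov,
                "coverage": cov,
            }
        )
        p = tmp_path / "rt.cov"
        write_bismark_coverage(calls, p)
        back = read_bismark_coverage(p)
        np.testing.assert_allclose(back["fraction"], calls["fraction"])
        assert back["coverage"].tolist() == calls["coverage"].tolist()
        assert back["pos"].tolist() == calls["pos"].tolist()
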