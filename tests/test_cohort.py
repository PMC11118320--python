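"""Variance filters, rank-distance clustering, bootstrap BP, occupancy."""
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

from epistate import (
    FeatureMatrix,
    GeneModel,
    GenomeLayout,
    IntervalSet,
    MarkSet,
    bootstrap_stability,
    hierarchical_cluster,
    occupancy_stats,
    promoter_occupancy_matrix,
    promoter_peak_width,
    variance_filter,
)
from epistate.cohort import _spearman_distance

from _oracles import bool_mask, random_interval_set


def _fm(values, index=None):
    df = pd.DataFrame(
        values, index=index or [f"s{i}" for i in range(len(values))]
    )
    df.columns = [f"f{i}" for i in range(df.shape[1])]
    return FeatureMatrix(values=df)


def _planted_fm(rng, n_per_group=4, n_feat=100, scale=10.0):
    muA = rng.normal(0, scale, n_feat)
    muB = rng.normal(0, scale, n_feat)
    X = np.vstack(
        [muA + rng.normal(0, 1, (n_per_group, n_feat)),
         muB + rng.normal(0, 1, (n_per_group, n_feat))]
    )
    return _fm(X)


class TestVarianceFilter:
    def test_top_fraction_keeps_exact_count(self, rng):
        fm = _fm(rng.normal(size=(5, 1000)))
        assert variance_filter(fm, "top_fraction", fraction=0.15).values.shape[1] == 150

    def test_top_fraction_one_is_identity(self, rng):
        fm = _fm(rng.normal(size=(5, 40)))
        assert variance_filter(fm, "top_fraction", fraction=1.0).values.equals(fm.values)

    def test_constant_feature_removed_by_std_over_mean(self):
        fm = _fm([[1.0, 5.0], [1.0, 1.0], [1.0, 9.0]])
        kept = variance_filter(fm, "std_over_mean").values.columns
        assert "f0" not in kept

    def test_low_signal_drops_features_low_everywhere(self):
        fm = _fm([[0.005, 0.5], [0.009, 0.001]])
        kept = variance_filter(fm, "low_signal", threshold=0.01).values.columns
        assert list(kept) == ["f1"]

    def test_bad_fraction_rejected(self, rng):
        fm = _fm(rng.normal(size=(3, 5)))
        with pytest.raises(ValueError):
            variance_filter(fm, "top_fraction", fraction=1.5)


class TestHierarchicalCluster:
    def test_identical_profiles_distance_zero_merged_first(self, rng):
        row = rng.normal(size=30)
        X = np.vstack([row, row, rng.normal(size=30)])
        res = hierarchical_cluster(_fm(X))
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert {int(res.linkage[0, 0]), int(res.linkage[0, 1])} == {0, 1}

    def test_anticorrelated_profiles_distance_two(self):
        x = np.arange(10.0)
        D = _spearman_distance(np.vstack([x, -x]))
        assert D[0, 1] == pytest.approx(2.0)

    def test_three_sample_ward_heights_by_lance_williams(self, rng):
        X = rng.normal(size=(3, 40))
        D = _spearman_distance(X)
        res = hierarchical_cluster(_fm(X))
        d12, d13, d23 = D[0, 1], D[0, 2], D[1, 2]
        pairs = {(0, 1): d12, (0, 2): d13, (1, 2): d23}
        (i, j), dmin = min(pairs.items(), key=lambda kv: kv[1])
        k = ({0, 1, 2} - {i, j}).pop()
        assert res.linkage[0, 2] == pytest.approx(dmin)
        # Ward.D2 update for the final merge of singleton k with pair {i,j}
        dik, djk = pairs[tuple(sorted((i, k)))], pairs[tuple(sorted((j, k)))]
        expected = np.sqrt((2 * dik**2 + 2 * djk**2 - dmin**2) / 3)
        assert res.linkage[1, 2] == pytest.approx(expected)

    def test_invariant_to_monotone_per_sample_transform(self, rng):
        fm = _planted_fm(rng)
        shifted = FeatureMatrix(values=np.exp(fm.values / 10) + 3)
        a = hierarchical_cluster(fm)
        b = hierarchical_cluster(shifted)
        np.testing.assert_allclose(a.linkage, b.linkage)

    def test_zero_variance_sample_error_names_sample(self):
        X = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0)[::-1]])
        with pytest.raises(ValueError, match="s0"):
            hierarchical_cluster(_fm(X))

    def test_newick_export_contains_all_samples(self, rng):
        fm = _planted_fm(rng)
        nwk = hierarchical_cluster(fm).to_newick()
        assert nwk.endswith(";") and all(f"s{i}" in nwk for i in range(8))


class TestBootstrapStability:
    def test_planted_structure_high_bp(self, rng):
        fm = _planted_fm(rng, scale=10.0)
        boot = bootstrap_stability(fm, n_boot=200, seed=0)
        assert boot.top_split_bp >= 95

    def test_pure_noise_unstable_majority_of_runs(self, rng):
        low = 0
        for seed in range(5):
            fm = _fm(rng.normal(size=(8, 100)))
            boot = bootstrap_stability(fm, n_boot=100, seed=seed)
            low += boot.top_split_bp < 70
        assert low >= 3

    def test_same_seed_identical_probabilities(self, rng):
        fm = _planted_fm(rng)
        a = bootstrap_stability(fm, n_boot=120, seed=5)
        b = bootstrap_stability(fm, n_boot=120, seed=5)
        assert a.node_table.equals(b.node_table)
        assert a.top_split_bp == b.top_split_bp

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_stability(_planted_fm(rng), n_boot=50)


class TestOccupancyStats:
    def test_fraction_and_counts(self):
        layout = GenomeLayout({"chr1": 1000})
        ms = MarkSet("s", {"H3K4me3": IntervalSet([("chr1", 0, 100)])})
        st = occupancy_stats(ms, "H3K4me3", layout)
        assert st.occupancy_fraction == 0.1
        assert st.n_peaks == 1 and st.widths.tolist() == [100]

    def test_empty_mark(self):
        layout = GenomeLayout({"chr1": 1000})
        ms = MarkSet("s", {"H3K4me3": IntervalSet()})
        st = occupancy_stats(ms, "H3K4me3", layout)
        assert st.occupancy_fraction == 0.0 and st.n_peaks == 0

    def test_occupancy_matches_per_base(self, rng):
        layout = GenomeLayout({"chrT": 100_000})
        for _ in range(10):
            iset = random_interval_set(rng)
            ms = MarkSet("s", {"m": iset})
            st = occupancy_stats(ms, "m", layout)
            assert st.occupancy_fraction == pytest.approx(
                bool_mask(iset, "chrT", 100_000).mean()
            )


class TestPromoterPeakWidth:
    GENES = [GeneModel("g", "chrT", "+", 10_000)]

    def test_mean_of_overlapping_peaks(self, toy_layout):
        ms = MarkSet(
            "s",
            {"H3K4me3": IntervalSet(
                [("chrT", 9000, 10_000), ("chrT", 11_000, 14_000),
                 ("chrT", 50_000, 50_100)]
            )},
        )
        got = promoter_peak_width(ms, "H3K4me3", self.GENES, toy_layout)
        assert got == pytest.approx(2000.0)  # mean of 1000 and 3000

    def test_no_overlap_missing(self, toy_layout):
        ms = MarkSet("s", {"H3K4me3": IntervalSet([("chrT", 50_000, 50_100)])})
        assert np.isnan(
            promoter_peak_width(ms, "H3K4me3", self.GENES, toy_layout)
        )

    def test_peak_spanning_two_promoters_counted_once(self, toy_layout):
        genes = [
            GeneModel("g1", "chrT", "+", 10_000),
            GeneModel("g2", "chrT", "+", 14_000),
        ]
        ms = MarkSet("s", {"m": IntervalSet([("chrT", 9_000, 15_000)])})
        assert promoter_peak_width(ms, "m", genes, toy_layout) == 6000.0


class TestPromoterOccupancyMatrix:
    def test_full_and_half_coverage(self, toy_layout):
        genes = [GeneModel("g", "chrT", "+", 10_000)]
        full = MarkSet("a", {"m": IntervalSet([("chrT", 0, 20_000)])})
        half = MarkSet("b", {"m": IntervalSet([("chrT", 8000, 10_000)])})
        fm = promoter_occupancy_matrix(
            [full, half], "m", genes, toy_layout, upstream=2000, downstream=2000
        )
        assert fm.values.loc["a", "g"] == 1.0
        assert fm.values.loc["b", "g"] == 0.5
        assert fm.provenance == "promoters"

    def test_entries_match_per_base_oracle(self, rng, toy_layout):
        genes = [
            GeneModel(f"g{i}", "chrT", "+-"[i % 2], int(p))
            for i, p in enumerate(rng.integers(3000, 97_000, size=12))
        ]
        cohort = [
            MarkSet(f"s{j}", {"m": random_interval_set(rng)}) for j in range(3)
        ]
        fm = promoter_occupancy_matrix(
            cohort, "m", genes, toy_layout, upstream=2000, downstream=300
        )
        from epistate.intervals import promoter_window

        for ms in cohort:
            mask = bool_mask(ms.marks["m"], "chrT", 100_000)
            for g in genes:
                w = promoter_window(g, 2000, 300, toy_layout)
                expected = mask[w.start: w.end].mean()
                assert fm.values.loc[ms.sample_id, g.gene_id] == pytest.approx(expected)
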