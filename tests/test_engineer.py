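"""Brute-force feature engineering and multicollinearity reduction."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gbfs.engineer import (
    FULL_OP_SET,
    BruteForceFeatureEngineer,
    CorrelationFilter,
    WardClusterReducer,
    brute_force_engineer,
    correlation_filter,
    engineered_feature_count,
    spearman_ward_cluster,
)


def enumerate_engineered(k, op_set):
    """Oracle: exhaustively enumerate engineered column identities."""
    cols = set()
    parents = [f"p{i}" for i in range(k)]
    for a, b in itertools.combinations(parents, 2):
        for op in ("sum", "abs_diff", "product"):
            if op in op_set:
                cols.add((op, frozenset((a, b))))
    if "ratio" in op_set:
        for a, b in itertools.permutations(parents, 2):
            cols.add(("ratio", (a, b)))
    return len(cols)


class TestBruteForce:
    def test_singleton_product_pair(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        out = brute_force_engineer(X, op_set=("product",), top_k=2)
        assert out.shape[1] == 1
        assert np.allclose(out.iloc[:, 0], X["a"] * X["b"])

    def test_full_op_set_count_small(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), columns=["a", "b"])
        assert brute_force_engineer(X, FULL_OP_SET, 2).shape[1] == 5

    @pytest.mark.parametrize("k", [2, 3, 5, 7])
    @pytest.mark.parametrize(
        "ops", [FULL_OP_SET, ("sum",), ("ratio",), ("sum", "product")]
    )
    def test_count_formula_matches_enumeration(self, rng, k, ops):
        X = pd.DataFrame(rng.normal(size=(4, k)), columns=[f"p{i}" for i in range(k)])
        out = brute_force_engineer(X, ops, k)
        expected = engineered_feature_count(k, ops)
        assert out.shape[1] == expected == enumerate_engineered(k, ops)

    def test_ratio_guard_keeps_entries_finite(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 4.0]})
        out = brute_force_engineer(X, ("ratio",), 2, ratio_epsilon=1e-9)
        assert np.isfinite(out.to_numpy()).all()
        assert out["a/b"].iloc[0] == pytest.approx(1.0 / 1e-9)

    def test_top_k_below_two_noop_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=5)})
        with pytest.warns(UserWarning):
            out = brute_force_engineer(X, FULL_OP_SET, 1)
        assert out.shape[1] == 0


class TestCorrelationFilter:
    def test_duplicate_column_reduced_to_one(self, rng):
        a = rng.normal(size=100)
        X = pd.DataFrame({"a": a, "dup": a.copy(), "b": rng.normal(size=100)})
        kept = correlation_filter(X, threshold=0.8)
        assert sorted(kept) == ["a", "b"]

    def test_ranked_mode_keeps_highest_priority_of_clique(self, rng):
        base = rng.normal(size=400)
        X = pd.DataFrame(
            {
                "f1": base + 0.1 * rng.normal(size=400),
                "f2": base + 0.1 * rng.normal(size=400),
                "f3": base + 0.1 * rng.normal(size=400),
            }
        )
        kept = correlation_filter(X, 0.8, priority=["f2", "f1", "f3"])
        assert kept == ["f2"]

    def test_strictly_below_threshold_retained(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=2000)
        b = 0.79 * a + np.sqrt(1 - 0.79**2) * rng.normal(size=2000)
        X = pd.DataFrame({"a": a, "b": b})
        r = abs(np.corrcoef(a, b)[0, 1])
        assume_ok = r < 0.8
        if assume_ok:
            assert sorted(correlation_filter(X, 0.8)) == ["a", "b"]

    def test_postcondition_no_retained_pair_above_threshold(self, small_features):
        X = small_features.iloc[:, :60]
        kept = correlation_filter(X, threshold=0.8)
        corr = np.abs(np.corrcoef(X[kept].to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        assert np.nanmax(corr) < 0.8

    def test_random_mode_seeded_and_valid(self, small_features):
        X = small_features.iloc[:, :40]
        k1 = correlation_filter(X, 0.8, mode="random", seed=5)
        k2 = correlation_filter(X, 0.8, mode="random", seed=5)
        assert k1 == k2
        corr = np.abs(np.corrcoef(X[k1].to_numpy(), rowvar=False))
        np.fill_diagonal(corr, 0.0)
        assert np.nanmax(corr) < 0.8

    def test_threshold_validated(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=5)})
        with pytest.raises(ValueError):
            correlation_filter(X, threshold=0.0)


class TestWardClustering:
    def test_identical_columns_share_cluster_one_retained(self, rng):
        a = rng.normal(size=200)
        X = pd.DataFrame({"a": a, "dup": a.copy(), "b": rng.normal(size=200)})
        out = spearman_ward_cluster(X, 0.5, priority=["a", "dup", "b"])
        assert out.feature_to_cluster["a"] == out.feature_to_cluster["dup"]
        assert "a" in out.retained and "dup" not in out.retained

    def test_independent_noise_stays_separate(self, rng):
        X = pd.DataFrame(rng.normal(size=(2000, 2)), columns=["a", "b"])
        out = spearman_ward_cluster(X, 0.5)
        assert out.feature_to_cluster["a"] != out.feature_to_cluster["b"]

    def test_exactly_one_representative_per_cluster(self, small_features):
        X = small_features.iloc[:, :50]
        out = spearman_ward_cluster(X, 0.5)
        n_clusters = len(set(out.feature_to_cluster.values()))
        assert len(out.retained) == n_clusters
        for feat, cid in out.feature_to_cluster.items():
            assert out.cluster_to_representative[cid] in out.feature_to_cluster

    def test_anticorrelated_features_cluster_together(self, rng):
        a = rng.normal(size=500)
        X = pd.DataFrame({"a": a, "nega": -a, "b": rng.normal(size=500)})
        out = spearman_ward_cluster(X, 0.5)
        assert out.feature_to_cluster["a"] == out.feature_to_cluster["nega"]

    def test_constant_column_isolated_with_warning(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50), "c": np.ones(50)})
        with pytest.warns(UserWarning):
            out = spearman_ward_cluster(X, 0.5)
        assert out.feature_to_cluster["a"] != out.feature_to_cluster["c"]


class TestTransformers:
    def test_engineer_then_filter_then_cluster_pipeline(self, small_features, rng):
        X = small_features.iloc[:, :30]
        eng = BruteForceFeatureEngineer(top_k=3).fit(X)
        Xe = eng.transform(X)
        assert Xe.shape[1] == X.shape[1] + engineered_feature_count(3)
        filt = CorrelationFilter(threshold=0.8).fit(Xe)
        Xf = filt.transform(Xe)
        red = WardClusterReducer(0.5).fit(Xf)
        Xr = red.transform(Xf)
        assert Xr.shape[1] == len(set(red.assignment_.feature_to_cluster.values()))
        assert Xr.shape[1] <= Xf.shape[1] <= Xe.shape[1]
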