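"""Gain ranking, F-statistic, mutual information and subset selection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.feature_selection import f_regression

from gbfs.relevance import (
    GainRelevanceSelector,
    anova_f_scores,
    gbdt_gain_ranking,
    incremental_subset_curve,
    knn_mutual_information,
    select_relevant,
)


def anova_decomposition_f(x, y):
    """Independent oracle: one-way ANOVA of y grouped by discrete x levels.

    For a discrete regressor the regression F on (1, n-2) df equals the
    ratio of explained to residual variance from the least-squares fit;
    computed here from the group-mean decomposition of the projection.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    # least squares slope/intercept
    b = np.cov(x, y, bias=True)[0, 1] / x.var()
    a = y.mean() - b * x.mean()
    fitted = a + b * x
    ss_reg = np.sum((fitted - y.mean()) ** 2)
    ss_res = np.sum((y - fitted) ** 2)
    return ss_reg / (ss_res / (n - 2))


class TestAnovaF:
    def test_closed_form_example(self):
        # r = 0.5, n = 102 -> F = 0.25 * 100 / 0.75
        rng = np.random.default_rng(0)
        # construct exact r = 0.5 via orthogonal components
        u = rng.normal(size=102)
        v = rng.normal(size=102)
        u = (u - u.mean()) / u.std()
        v = v - v.mean()
        v -= u * (u @ v) / (u @ u)
        v /= v.std()
        y = 0.5 * u + np.sqrt(1 - 0.25) * v
        out = anova_f_scores(pd.DataFrame({"x": u}), y)
        assert out["f_stat"].iloc[0] == pytest.approx(0.25 * 100 / 0.75, rel=1e-9)

    def test_zero_association_zero_f(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        out = anova_f_scores(pd.DataFrame({"x": x}), y)
        assert out["f_stat"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_f_regression(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 6)), columns=list("abcdef"))
        y = rng.normal(size=80)
        ours = anova_f_scores(X, y)["f_stat"].to_numpy()
        ref, _ = f_regression(X, y)
        assert np.allclose(ours, ref, rtol=1e-9)

    def test_matches_anova_decomposition_on_discrete_groups(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, size=60).astype(float)
            y = 0.7 * x + rng.normal(size=60)
            ours = anova_f_scores(pd.DataFrame({"x": x}), y)["f_stat"].iloc[0]
            assert ours == pytest.approx(anova_decomposition_f(x, y), rel=1e-9)

    def test_zero_variance_degenerate_not_error(self):
        X = pd.DataFrame({"c": [1.0, 1.0, 1.0], "x": [1.0, 2.0, 3.0]})
        out = anova_f_scores(X, [1.0, 2.0, 4.0])
        assert out.loc[out.feature == "c", "f_stat"].iloc[0] == 0.0
        assert bool(out.loc[out.feature == "c", "f_degenerate"].iloc[0])

    def test_normalization_and_scale_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = X["a"] + 0.1 * rng.normal(size=50)
        out = anova_f_scores(X, y)
        assert out["f_stat_normalized"].max() == pytest.approx(1.0)
        X2 = X.copy()
        X2["a"] = X2["a"] * 1000.0
        out2 = anova_f_scores(X2, y)
        assert np.allclose(out["f_stat"], out2["f_stat"], rtol=1e-9)


class TestMutualInformation:
    def test_identical_feature_attains_normalized_max(self, rng):
        y = rng.normal(size=1000)
        X = pd.DataFrame({"same": y.copy(), "noise": rng.normal(size=1000)})
        out = knn_mutual_information(X, y, k=3, seed=0)
        assert out.loc[out.feature == "same", "mi_normalized"].iloc[0] == 1.0

    def test_independent_feature_near_zero(self, rng):
        y = rng.normal(size=1000)
        X = pd.DataFrame({"ind": rng.normal(size=1000)})
        mi = knn_mutual_information(X, y, k=3, seed=0)["mi"].iloc[0]
        assert abs(mi) < 0.05

    def test_k_bounds(self, rng):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            knn_mutual_information(X, [1, 2, 3], k=0)
        with pytest.raises(ValueError):
            knn_mutual_information(X, [1, 2, 3], k=3)


class TestGainRanking:
    def test_generative_feature_has_max_gain(self, linear_toy):
        X, y = linear_toy
        out = gbdt_gain_ranking(X, y, seed=0)
        assert out.sort_values("gain_rank")["feature"].iloc[0] == "x0"

    def test_constant_feature_zero_gain(self, linear_toy):
        X, y = linear_toy
        X = X.copy()
        X["const"] = 1.0
        out = gbdt_gain_ranking(X, y, seed=0)
        assert out.loc[out.feature == "const", "gain"].iloc[0] == 0.0

    def test_ranks_are_permutation(self, linear_toy):
        X, y = linear_toy
        out = gbdt_gain_ranking(X, y, seed=0)
        assert sorted(out["gain_rank"]) == list(range(1, len(X.columns) + 1))

    def test_top_ranking_invariant_to_column_order(self, linear_toy):
        # the histogram booster breaks ties between near-zero-gain noise
        # columns by position, so only meaningful gains are order-stable
        X, y = linear_toy
        a = gbdt_gain_ranking(X, y, seed=0)
        b = gbdt_gain_ranking(X[list(X.columns)[::-1]], y, seed=0)
        top_a = a.sort_values("gain_rank")["feature"].iloc[0]
        top_b = b.sort_values("gain_rank")["feature"].iloc[0]
        assert top_a == top_b == "x0"
        ga = a.set_index("feature")["gain"]
        gb = b.set_index("feature")["gain"]
        assert ga["x0"] == pytest.approx(gb["x0"], rel=1e-6)

    def test_nonfinite_rejected(self):
        X = pd.DataFrame({"x": [1.0, np.nan, 2.0]})
        with pytest.raises(ValueError):
            gbdt_gain_ranking(X, [1.0, 2.0, 3.0])


class TestSelection:
    def _scores(self):
        return pd.DataFrame(
            {
                "feature": list("abcde"),
                "gain": [10.0, 8.0, 5.0, 1.0, 0.0],
                "gain_rank": [1, 2, 3, 4, 5],
                "f_stat": [9.0, 7.0, 1.0, 0.5, 8.0],
                "f_stat_normalized": [1.0, 0.78, 0.11, 0.06, 0.89],
                "mi": [1.0, 0.2, 0.1, 0.0, 0.95],
                "mi_normalized": [1.0, 0.2, 0.1, 0.0, 0.95],
            }
        )

    def test_pure_gain_policy(self):
        assert select_relevant(self._scores(), n_gain=3, n_stat=0) == ["a", "b", "c"]

    def test_union_includes_statistical_rescues(self):
        out = select_relevant(self._scores(), n_gain=2, n_stat=5, min_normalized=0.9)
        assert "e" in out and out[:2] == ["a", "b"]

    def test_empty_selection_raises(self):
        with pytest.raises(ValueError):
            select_relevant(self._scores(), n_gain=0, n_stat=0)


class TestSubsetCurve:
    def test_sizes_enumerate_step_multiples(self, linear_toy):
        X, y = linear_toy
        curve = incremental_subset_curve(
            X, y, step=7, gbdt_params={"n_estimators": 50}, seed=0
        )
        sizes = sorted(curve["size"].unique())
        assert sizes == [7, 14, 21]
        assert set(curve["partition"]) == {"train", "validation"}

    def test_flat_after_informative_feature(self, linear_toy):
        X, y = linear_toy
        curve = incremental_subset_curve(
            X,
            y,
            ranking=["x0"] + [f"x{i}" for i in range(1, 21)],
            step=5,
            gbdt_params={"n_estimators": 100},
            seed=0,
        )
        val = curve[curve.partition == "validation"].set_index("size")["rmse"]
        assert val.iloc[-1] >= 0.5 * val.iloc[0]

    def test_step_validated(self, linear_toy):
        X, y = linear_toy
        with pytest.raises(ValueError):
            incremental_subset_curve(X, y, step=0)


class TestSelectorEstimator:
    def test_fit_transform_selects_generative_feature(self, linear_toy):
        X, y = linear_toy
        sel = GainRelevanceSelector(
            n_gain=5, n_stat=2, gbdt_params={"n_estimators": 100}, seed=0
        )
        Xt = sel.fit(X, y).transform(X)
        assert "x0" in Xt.columns
        assert Xt.shape[1] <= 7
        mask = sel._get_support_mask()
        assert mask.sum() == Xt.shape[1]

    def test_sklearn_param_interface(self):
        sel = GainRelevanceSelector(n_gain=10)
        assert sel.get_params()["n_gain"] == 10
        sel.set_params(n_gain=20)
        assert sel.n_gain == 20
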