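"""Feature relevance ranking: GBDT gain, ANOVA F-statistic, k-NN MI.

Two parallel relevance signals drive the first selection stage:

* **Gain ranking** — total objective loss reduction attributed to splits
  on each feature over a full GBDT ensemble trained on all features.
* **Statistical association** — the regression F-statistic obtained by
  transforming the Pearson correlation r between feature and target,
  F = r^2 (n-2) / (1 - r^2) on (1, n-2) degrees of freedom, and a
  k-nearest-neighbor mutual information estimate. Both are normalized by
  their maximum so the top feature scores exactly 1, and are used as
  rankings, not significance cutoffs.

For classification the F analog uses the point-biserial r (identical
formula) and the discrete-target k-NN MI variant.

The selected subset is the union of the top ``n_gain`` gain features
with the features whose normalized F or MI exceeds ``min_normalized``
(capped at ``n_stat``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.feature_selection import (
    mutual_info_classif,
    mutual_info_regression,
)
from sklearn.model_selection import train_test_split

from ._gbdt import feature_gain, make_gbdt, validate_matrix
from . import metrics as M


def gbdt_gain_ranking(
    X: pd.DataFrame,
    y,
    task_type: str = "regression",
    gbdt_params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-feature total gain from one GBDT trained on all features.

    Features never used in a split get gain 0. Ties in gain are broken
    by column order, which makes the ranking deterministic under a fixed
    seed.
    """
    X = validate_matrix(X)
    model = make_gbdt(task_type, gbdt_params, seed)
    model.fit(X, np.asarray(y))
    gain = feature_gain(model)
    out = pd.DataFrame({"feature": X.columns, "gain": gain})
    order = np.lexsort((np.arange(len(out)), -out["gain"].to_numpy()))
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["gain_rank"] = ranks
    return out


def anova_f_scores(X: pd.DataFrame, y) -> pd.DataFrame:
    """Regression F-statistic per feature via the Pearson-r transform.

    Zero-variance features get F = 0 with a degenerate flag instead of a
    division by zero.
    """
    X = validate_matrix(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xv = X.to_numpy(dtype=float)
    yc = y - y.mean()
    xc = Xv - Xv.mean(axis=0)
    sx = np.sqrt(np.mean(xc**2, axis=0))
    sy = np.sqrt(np.mean(yc**2))
    degenerate = sx == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(
            degenerate | (sy == 0), 0.0, (xc * yc[:, None]).mean(axis=0) / (sx * sy)
        )
        r = np.clip(r, -1.0, 1.0)
        f = np.where(np.abs(r) >= 1.0, np.inf, r**2 * (n - 2) / (1 - r**2))
    f = np.where(degenerate, 0.0, f)
    fmax = np.max(f[np.isfinite(f)], initial=0.0)
    finite_f = np.where(np.isfinite(f), f, fmax if fmax > 0 else 1.0)
    norm = finite_f / finite_f.max() if finite_f.max() > 0 else finite_f
    return pd.DataFrame(
        {
            "feature": X.columns,
            "f_stat": finite_f,
            "f_stat_normalized": norm,
            "f_degenerate": degenerate,
        }
    )


def knn_mutual_information(
    X: pd.DataFrame,
    y,
    k: int = 3,
    seed: int = 0,
    task_type: str = "regression",
) -> pd.DataFrame:
    """k-NN mutual information per feature (nats), normalized by the max.

    Negative estimates are clipped to 0; seeded jitter inside the
    estimator breaks ties in discrete columns.
    """
    X = validate_matrix(X)
    y = np.asarray(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= len(y):
        raise ValueError("k must be smaller than the sample count")
    if task_type == "classification":
        mi = mutual_info_classif(
            X, y.astype(int), n_neighbors=k, random_state=seed
        )
    else:
        mi = mutual_info_regression(X, y, n_neighbors=k, random_state=seed)
    mi = np.clip(mi, 0.0, None)
    norm = mi / mi.max() if mi.max() > 0 else mi
    return pd.DataFrame(
        {"feature": X.columns, "mi": mi, "mi_normalized": norm}
    )


def compute_feature_scores(
    X: pd.DataFrame,
    y,
    task_type: str = "regression",
    gbdt_params: dict | None = None,
    mi_k: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Full score table: gain, gain_rank, F, MI and normalized variants."""
    gain = gbdt_gain_ranking(X, y, task_type, gbdt_params, seed)
    f = anova_f_scores(X, y)
    mi = knn_mutual_information(X, y, k=mi_k, seed=seed, task_type=task_type)
    out = gain.merge(f, on="feature").merge(mi, on="feature")
    # re-break gain ties by higher F, then column order
    order = np.lexsort(
        (
            np.arange(len(out)),
            -out["f_stat"].to_numpy(),
            -out["gain"].to_numpy(),
        )
    )
    ranks = np.empty(len(out), dtype=int)
    ranks[order] = np.arange(1, len(out) + 1)
    out["gain_rank"] = ranks
    return out


def select_relevant(
    scores: pd.DataFrame,
    n_gain: int = 150,
    n_stat: int = 50,
    min_normalized: float = 0.9,
) -> list[str]:
    """Union of top-gain features with strongly associated features.

    Returns the top ``n_gain`` features by gain rank plus up to
    ``n_stat`` further features whose normalized F or MI is at least
    ``min_normalized``, ordered by gain rank. Deterministic given the
    score table.
    """
    ranked = scores.sort_values("gain_rank")
    chosen = list(ranked["feature"].head(n_gain))
    if n_stat > 0:
        stat_score = ranked[["f_stat_normalized", "mi_normalized"]].max(axis=1)
        extras = ranked.loc[
            (stat_score >= min_normalized) & (~ranked["feature"].isin(chosen))
        ]
        extras = extras.assign(_s=stat_score[extras.index]).sort_values(
            "_s", ascending=False
        )
        chosen += list(extras["feature"].head(n_stat))
        chosen = [f for f in ranked["feature"] if f in set(chosen)]
    if not chosen:
        raise ValueError("empty feature selection")
    return chosen


def incremental_subset_curve(
    X: pd.DataFrame,
    y,
    ranking: list[str] | None = None,
    step: int = 10,
    validation_fraction: float = 0.2,
    task_type: str = "regression",
    gbdt_params: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train/validation metric curves over growing top-k feature subsets.

    A GBDT is trained on the top ``size`` features (by gain order) for
    sizes step, 2*step, ..., capped at the feature count, and MAE, RMSE
    and R^2 are recorded on the training and held-out validation
    partitions.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    X = validate_matrix(X)
    y = np.asarray(y, dtype=float)
    if ranking is None:
        ranking = list(
            gbdt_gain_ranking(X, y, task_type, gbdt_params, seed)
            .sort_values("gain_rank")["feature"]
        )
    idx_train, idx_val = train_test_split(
        np.arange(len(y)), test_size=validation_fraction, random_state=seed
    )
    sizes = list(range(step, len(ranking), step)) + [len(ranking)]
    sizes = sorted(set(sizes))
    records = []
    for size in sizes:
        cols = ranking[:size]
        model = make_gbdt(task_type, gbdt_params, seed)
        model.fit(X.iloc[idx_train][cols], y[idx_train])
        for part, idx in (("train", idx_train), ("validation", idx_val)):
            pred = model.predict(X.iloc[idx][cols])
            records.append(
                {
                    "size": size,
                    "partition": part,
                    "mae": M.mae(y[idx], pred),
                    "rmse": M.rmse(y[idx], pred),
                    "r2": M.r_squared(y[idx], pred),
                }
            )
    return pd.DataFrame(records)


class GainRelevanceSelector(SelectorMixin, BaseEstimator):
    """First-stage relevance selector (gain union statistical scores).

    Fitted attributes
    -----------------
    scores_ : DataFrame
        The full feature score table.
    selected_features_ : list of str
        Features retained by :func:`select_relevant`.
    """

    def __init__(
        self,
        n_gain: int = 150,
        n_stat: int = 50,
        min_normalized: float = 0.9,
        mi_k: int = 3,
        task_type: str = "regression",
        gbdt_params: dict | None = None,
        seed: int = 0,
    ):
        self.n_gain = n_gain
        self.n_stat = n_stat
        self.min_normalized = min_normalized
        self.mi_k = mi_k
        self.task_type = task_type
        self.gbdt_params = gbdt_params
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_matrix(X)
        self.feature_names_in_ = np.asarray(X.columns)
        self.n_features_in_ = X.shape[1]
        self.scores_ = compute_feature_scores(
            X,
            y,
            task_type=self.task_type,
            gbdt_params=self.gbdt_params,
            mi_k=self.mi_k,
            seed=self.seed,
        )
        self.selected_features_ = select_relevant(
            self.scores_, self.n_gain, self.n_stat, self.min_normalized
        )
        return self

    def _get_support_mask(self) -> np.ndarray:
        sel = set(self.selected_features_)
        return np.asarray([f in sel for f in self.feature_names_in_])

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]
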