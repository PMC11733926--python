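"""Brute-force feature engineering and multicollinearity reduction.

Engineering needs no domain knowledge: for the ``top_k`` most relevant
features every unordered pair contributes a sum, an absolute difference
and a product, and every ordered pair a guarded ratio, so the engineered
count is ``3 C(k,2) + k(k-1)`` for the full operation set.

Redundancy is then removed in two steps, in a fixed order:

1. a greedy correlation filter drops one member of every pair with
   |Pearson r| at or above the threshold (default 0.8) — the
   lower-priority member in ranked mode, a seeded coin in random mode;
2. hierarchical agglomerative clustering of the surviving features on
   the distance 1 - |Spearman rho| with Ward linkage, cutting the tree
   at a fixed linkage distance (default 0.5) and keeping one
   representative (best gain rank) per cluster. Absolute rho is used so
   strongly anticorrelated features — equally redundant for trees —
   cluster together.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, TransformerMixin

from ._gbdt import validate_matrix

FULL_OP_SET = ("sum", "abs_diff", "product", "ratio")

_OP_FMT = {
    "sum": "{a}+{b}",
    "abs_diff": "|{a}-{b}|",
    "product": "{a}*{b}",
    "ratio": "{a}/{b}",
}


def engineered_feature_count(top_k: int, op_set=FULL_OP_SET) -> int:
    """Closed-form engineered-column count for ``top_k`` parents."""
    if top_k < 2:
        return 0
    pairs = top_k * (top_k - 1) // 2
    count = sum(pairs for op in op_set if op in ("sum", "abs_diff", "product"))
    if "ratio" in op_set:
        count += top_k * (top_k - 1)
    return count


def brute_force_engineer(
    X_subset: pd.DataFrame,
    op_set=FULL_OP_SET,
    top_k: int | None = None,
    ratio_epsilon: float = 1e-9,
    parent_order: list[str] | None = None,
) -> pd.DataFrame:
    """Engineered columns from pairwise combinations of the top parents.

    ``parent_order`` (default: column order) defines which features
    count as the ``top_k``. Ratio denominators with magnitude below
    ``ratio_epsilon`` are replaced by ``ratio_epsilon`` (signed), so
    every engineered entry is finite.
    """
    X_subset = validate_matrix(X_subset)
    parents = parent_order if parent_order is not None else list(X_subset.columns)
    if top_k is None:
        top_k = len(parents)
    if top_k > len(parents):
        raise ValueError("top_k exceeds the number of available parents")
    if top_k < 2:
        warnings.warn("top_k < 2: no engineered features")
        return pd.DataFrame(index=X_subset.index)
    parents = parents[:top_k]
    cols: dict[str, np.ndarray] = {}
    parent_map: dict[str, tuple[str, str]] = {}
    for i, a in enumerate(parents):
        va = X_subset[a].to_numpy(dtype=float)
        for b in parents[i + 1 :]:
            vb = X_subset[b].to_numpy(dtype=float)
            if "sum" in op_set:
                name = _OP_FMT["sum"].format(a=a, b=b)
                cols[name] = va + vb
                parent_map[name] = (a, b)
            if "abs_diff" in op_set:
                name = _OP_FMT["abs_diff"].format(a=a, b=b)
                cols[name] = np.abs(va - vb)
                parent_map[name] = (a, b)
            if "product" in op_set:
                name = _OP_FMT["product"].format(a=a, b=b)
                cols[name] = va * vb
                parent_map[name] = (a, b)
    if "ratio" in op_set:
        for a in parents:
            va = X_subset[a].to_numpy(dtype=float)
            for b in parents:
                if a == b:
                    continue
                vb = X_subset[b].to_numpy(dtype=float)
                denom = np.where(
                    np.abs(vb) < ratio_epsilon,
                    np.where(vb < 0, -ratio_epsilon, ratio_epsilon),
                    vb,
                )
                name = _OP_FMT["ratio"].format(a=a, b=b)
                cols[name] = va / denom
                parent_map[name] = (a, b)
    out = pd.DataFrame(cols, index=X_subset.index)
    out.attrs["parents"] = parent_map
    return out


def correlation_filter(
    X: pd.DataFrame,
    threshold: float = 0.8,
    priority: list[str] | None = None,
    mode: str = "ranked",
    seed: int = 0,
) -> list[str]:
    """Greedy elimination of highly correlated features.

    Features are visited in priority order (ranked mode) or a seeded
    random order (random mode); a feature is kept only if its |Pearson
    r| with every already-kept feature stays below the threshold. The
    post-condition — no retained pair with |r| >= threshold — holds in
    both modes. Returns the retained features in original column order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    X = validate_matrix(X)
    cols = list(X.columns)
    if mode == "random":
        rng = np.random.default_rng(seed)
        order = [cols[i] for i in rng.permutation(len(cols))]
    elif mode == "ranked":
        order = list(priority) if priority is not None else cols
        order = [c for c in order if c in set(cols)]
        order += [c for c in cols if c not in set(order)]
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X.to_numpy(dtype=float), rowvar=False)
    corr = np.nan_to_num(np.abs(corr), nan=0.0)
    pos = {c: i for i, c in enumerate(cols)}
    kept: list[str] = []
    for c in order:
        i = pos[c]
        if all(corr[i, pos[k]] < threshold for k in kept):
            kept.append(c)
    kept_set = set(kept)
    return [c for c in cols if c in kept_set]


@dataclass
class ClusterAssignment:
    """Feature -> cluster map with one representative per cluster."""

    feature_to_cluster: dict[str, int]
    cluster_to_representative: dict[int, str]
    linkage_threshold: float
    linkage_matrix: np.ndarray = field(repr=False, default=None)

    @property
    def retained(self) -> list[str]:
        return list(self.cluster_to_representative.values())


def spearman_ward_cluster(
    X: pd.DataFrame,
    linkage_threshold: float = 0.5,
    priority: list[str] | None = None,
) -> ClusterAssignment:
    """Ward clustering on 1 - |Spearman rho| with a fixed cut height.

    One representative per cluster is retained: the best (earliest) in
    ``priority``, or the first by column order. Constant columns have
    undefined rho; they are isolated into their own cluster with a
    warning by assigning them maximal distance to everything.
    """
    X = validate_matrix(X)
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns to cluster")
    rho = spearmanr(X.to_numpy(dtype=float)).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-column case
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    if np.isnan(rho).any():
        warnings.warn("constant column(s): isolating into singleton clusters")
        rho = np.nan_to_num(rho, nan=0.0)
    dist = 1.0 - np.abs(rho)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2  # enforce exact symmetry
    Z = linkage(squareform(dist, checks=False), method="ward")
    labels = fcluster(Z, t=linkage_threshold, criterion="distance")
    rank = {c: i for i, c in enumerate(priority)} if priority else {}
    feature_to_cluster = dict(zip(cols, (int(l) for l in labels)))
    reps: dict[int, str] = {}
    for cluster_id in sorted(set(feature_to_cluster.values())):
        members = [c for c in cols if feature_to_cluster[c] == cluster_id]
        members.sort(key=lambda c: (rank.get(c, len(cols)), cols.index(c)))
        reps[cluster_id] = members[0]
    return ClusterAssignment(
        feature_to_cluster=feature_to_cluster,
        cluster_to_representative=reps,
        linkage_threshold=linkage_threshold,
        linkage_matrix=Z,
    )


class BruteForceFeatureEngineer(BaseEstimator, TransformerMixin):
    """Appends engineered pairwise-combination columns to the matrix."""

    def __init__(
        self,
        top_k: int = 7,
        op_set=FULL_OP_SET,
        ratio_epsilon: float = 1e-9,
        parent_order: list[str] | None = None,
    ):
        self.top_k = top_k
        self.op_set = op_set
        self.ratio_epsilon = ratio_epsilon
        self.parent_order = parent_order

    def fit(self, X: pd.DataFrame, y=None):
        X = validate_matrix(X)
        parents = self.parent_order or list(X.columns)
        self.parents_ = parents[: min(self.top_k, len(parents))]
        probe = brute_force_engineer(
            X.head(1), self.op_set, len(self.parents_), self.ratio_epsilon,
            self.parents_,
        )
        self.engineered_names_ = list(probe.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = validate_matrix(X)
        eng = brute_force_engineer(
            X, self.op_set, len(self.parents_), self.ratio_epsilon, self.parents_
        )
        return pd.concat([X, eng], axis=1)


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Pairwise |r| filter; learns the retained columns on fit."""

    def __init__(
        self,
        threshold: float = 0.8,
        mode: str = "ranked",
        priority: list[str] | None = None,
        seed: int = 0,
    ):
        self.threshold = threshold
        self.mode = mode
        self.priority = priority
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        self.retained_ = correlation_filter(
            X, self.threshold, self.priority, self.mode, self.seed
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.retained_]


class WardClusterReducer(BaseEstimator, TransformerMixin):
    """Spearman/Ward cluster reduction; keeps one representative each."""

    def __init__(
        self, linkage_threshold: float = 0.5, priority: list[str] | None = None
    ):
        self.linkage_threshold = linkage_threshold
        self.priority = priority

    def fit(self, X: pd.DataFrame, y=None):
        self.assignment_ = spearman_ward_cluster(
            X, self.linkage_threshold, self.priority
        )
        cols = list(pd.DataFrame(X).columns)
        retained = set(self.assignment_.retained)
        self.retained_ = [c for c in cols if c in retained]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.retained_]
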