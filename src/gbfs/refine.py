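"""Permutation importance and cross-validated recursive feature elimination.

Permutation importance is the drop in a model's score when one feature
column is shuffled (``n_repeats`` seeded shuffles per feature; the
reported ``mean_drop`` is baseline score minus mean permuted score, so
positive values mean the model relies on the feature).

RFE runs a greedy backward search: at each round the features with the
lowest GBDT gain — recomputed on the surviving set — are eliminated, and
the k-fold cross-validated metric (default negative RMSE) is recorded at
every visited subset size. The final subset is the one at the size with
the best mean CV score, smallest size winning ties. With step 1 the
visited sets are strictly nested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance as _sk_permutation
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score

from ._gbdt import feature_gain, make_gbdt, validate_matrix

_SCORING = {
    "neg_rmse": "neg_root_mean_squared_error",
    "neg_mae": "neg_mean_absolute_error",
    "r2": "r2",
    "auc": "roc_auc",
    "accuracy": "accuracy",
}


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    metric: str = "neg_rmse",
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean and std score drop per feature over seeded shuffles."""
    if metric not in _SCORING:
        raise ValueError(f"unknown metric: {metric!r}")
    X = validate_matrix(X)
    result = _sk_permutation(
        model,
        X,
        np.asarray(y),
        scoring=_SCORING[metric],
        n_repeats=n_repeats,
        random_state=seed,
        n_jobs=1,
    )
    return pd.DataFrame(
        {
            "feature": X.columns,
            "mean_drop": result.importances_mean,
            "std_drop": result.importances_std,
            "n_repeats": n_repeats,
        }
    ).sort_values("mean_drop", ascending=False, kind="stable").reset_index(drop=True)


@dataclass
class RFEReport:
    """Trajectory of the backward elimination."""

    subset_sizes: list[int]
    cv_mean: list[float]
    cv_std: list[float]
    selected_features: list[str]
    optimal_size: int
    elimination_order: list[str] = field(default_factory=list)
    feature_order: list[str] = field(default_factory=list)

    def features_at(self, size: int) -> list[str]:
        """The surviving feature set at any visited size (nested)."""
        if size not in self.subset_sizes:
            raise ValueError(f"size {size} was not visited")
        n_removed = len(self.feature_order) - size
        removed = set(self.elimination_order[:n_removed])
        return [f for f in self.feature_order if f not in removed]

    def to_json(self) -> dict:
        return {
            "subset_sizes": self.subset_sizes,
            "cv_mean": self.cv_mean,
            "cv_std": self.cv_std,
            "selected_features": self.selected_features,
            "optimal_size": self.optimal_size,
            "elimination_order": self.elimination_order,
        }


def recursive_feature_elimination(
    X: pd.DataFrame,
    y,
    task_type: str = "regression",
    estimator_params: dict | None = None,
    cv_folds: int = 10,
    metric: str = "neg_rmse",
    step: int = 1,
    seed: int = 0,
    min_size: int = 1,
    within_se: float = 1.0,
) -> RFEReport:
    """Greedy gain-guided backward elimination with k-fold CV scoring.

    The optimal size is the smallest visited size whose mean CV score is
    within ``within_se`` fold standard errors of the best mean — the
    most compact subset showing no degradation in performance. Setting
    ``within_se=0`` selects the strict best mean (ties to smallest).
    """
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    if step < 1:
        raise ValueError("step must be >= 1")
    if metric not in _SCORING:
        raise ValueError(f"unknown metric: {metric!r}")
    X = validate_matrix(X)
    if X.shape[1] < step:
        raise ValueError("feature matrix narrower than the elimination step")
    y = np.asarray(y)
    if task_type == "classification":
        cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
    else:
        cv = KFold(cv_folds, shuffle=True, random_state=seed)

    current = list(X.columns)
    sizes: list[int] = []
    means: list[float] = []
    stds: list[float] = []
    eliminated: list[str] = []
    while True:
        model = make_gbdt(task_type, estimator_params, seed)
        scores = cross_val_score(
            model, X[current], y, cv=cv, scoring=_SCORING[metric], n_jobs=1
        )
        sizes.append(len(current))
        means.append(float(scores.mean()))
        stds.append(float(scores.std()))
        if len(current) <= min_size:
            break
        fit_model = make_gbdt(task_type, estimator_params, seed)
        fit_model.fit(X[current], y)
        gain = feature_gain(fit_model)
        n_drop = min(step, len(current) - min_size)
        # lowest gain first; ties by later column order so earlier
        # (higher-priority) features survive
        order = np.lexsort((-np.arange(len(current)), gain))
        drop = [current[i] for i in order[:n_drop]]
        eliminated.extend(drop)
        dropset = set(drop)
        current = [c for c in current if c not in dropset]

    best = int(np.argmax(means))
    tol = within_se * stds[best] / np.sqrt(cv_folds) + 1e-12
    # smallest size within tolerance of the best (sizes are decreasing)
    for i in range(len(means) - 1, -1, -1):
        if means[i] >= means[best] - tol:
            best = i
            break
    optimal_size = sizes[best]
    feature_order = list(X.columns)
    removed = set(eliminated[: len(feature_order) - optimal_size])
    selected = [f for f in feature_order if f not in removed]
    return RFEReport(
        subset_sizes=sizes,
        cv_mean=means,
        cv_std=stds,
        selected_features=selected,
        optimal_size=optimal_size,
        elimination_order=eliminated,
        feature_order=feature_order,
    )


class GainRFE:
    """Estimator-shaped wrapper around the backward elimination.

    Fitted attributes: ``report_`` (the :class:`RFEReport`) and
    ``selected_features_``.
    """

    def __init__(
        self,
        task_type: str = "regression",
        estimator_params: dict | None = None,
        cv_folds: int = 10,
        metric: str = "neg_rmse",
        step: int = 1,
        seed: int = 0,
        min_size: int = 1,
    ):
        self.task_type = task_type
        self.estimator_params = estimator_params
        self.cv_folds = cv_folds
        self.metric = metric
        self.step = step
        self.seed = seed
        self.min_size = min_size

    def get_params(self, deep=True):
        return {
            k: getattr(self, k)
            for k in (
                "task_type",
                "estimator_params",
                "cv_folds",
                "metric",
                "step",
                "seed",
                "min_size",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: pd.DataFrame, y=None):
        self.report_ = recursive_feature_elimination(
            X,
            y,
            task_type=self.task_type,
            estimator_params=self.estimator_params,
            cv_folds=self.cv_folds,
            metric=self.metric,
            step=self.step,
            seed=self.seed,
            min_size=self.min_size,
        )
        self.selected_features_ = self.report_.selected_features
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]

    def fit_transform(self, X, y=None):
        return self.fit(X, y).transform(X)
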