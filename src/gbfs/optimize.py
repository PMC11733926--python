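"""Two-step hyperparameter optimization and the final predictive model.

A coarse grid search first brackets a promising region of the
hyperparameter space; Bayesian optimization (Gaussian-process surrogate
with an expected-improvement acquisition, seeded random candidate pools)
then fine-tunes within it. The cross-validation objective is minimized:
RMSE for regression, 1 - AUC-ROC for classification.

The GBFS-Mol2Vec variant differs from plain GBFS only here: the Mol2Vec
embedding columns are concatenated onto the selected descriptor features
(:func:`attach_embeddings`) immediately before optimization, leaving the
selection-stage artifacts untouched.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score
from scipy.stats import norm

from ._gbdt import make_gbdt, validate_matrix


@dataclass
class Param:
    """One hyperparameter dimension."""

    name: str
    type: str  # integer | real | log-real | categorical
    bounds: tuple | None = None
    choices: Sequence | None = None

    def __post_init__(self):
        if self.type == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: categorical needs choices")
        else:
            lo, hi = self.bounds
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{self.name}: bounds must be finite and ordered")
            if self.type == "log-real" and lo <= 0:
                raise ValueError(f"{self.name}: log-real bounds must be positive")


@dataclass
class HyperparameterSpace:
    params: list[Param]

    def __post_init__(self):
        names = [p.name for p in self.params]
        if len(set(names)) != len(names):
            raise ValueError("duplicate hyperparameter names")

    def sample(self, rng: np.random.Generator) -> dict:
        point = {}
        for p in self.params:
            if p.type == "categorical":
                point[p.name] = p.choices[rng.integers(len(p.choices))]
            elif p.type == "integer":
                point[p.name] = int(rng.integers(p.bounds[0], p.bounds[1] + 1))
            elif p.type == "log-real":
                point[p.name] = float(
                    np.exp(rng.uniform(np.log(p.bounds[0]), np.log(p.bounds[1])))
                )
            else:
                point[p.name] = float(rng.uniform(*p.bounds))
        return point

    def encode(self, point: dict) -> np.ndarray:
        """Map a point into [0, 1]^d for the surrogate."""
        x = []
        for p in self.params:
            v = point[p.name]
            if p.type == "categorical":
                x.append(list(p.choices).index(v) / max(len(p.choices) - 1, 1))
            elif p.type == "log-real":
                lo, hi = np.log(p.bounds[0]), np.log(p.bounds[1])
                x.append((np.log(v) - lo) / (hi - lo))
            else:
                lo, hi = p.bounds
                x.append((v - lo) / (hi - lo))
        return np.asarray(x)


#: default search space for the final GBDT
DEFAULT_SPACE = HyperparameterSpace(
    [
        Param("learning_rate", "log-real", (0.005, 0.3)),
        Param("n_estimators", "integer", (100, 3000)),
        Param("num_leaves", "integer", (15, 255)),
        Param("min_child_samples", "integer", (5, 100)),
        Param("subsample", "real", (0.5, 1.0)),
        Param("colsample_bytree", "real", (0.5, 1.0)),
        Param("reg_alpha", "log-real", (1e-8, 10.0)),
        Param("reg_lambda", "log-real", (1e-8, 10.0)),
    ]
)


@dataclass
class OptimizationTrace:
    """Ordered (point, objective) evaluations; minimization convention."""

    points: list[dict] = field(default_factory=list)
    values: list[float] = field(default_factory=list)
    seed: int = 0

    def record(self, point: dict, value: float) -> None:
        self.points.append(point)
        self.values.append(float(value))

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.values))

    @property
    def best_point(self) -> dict:
        return self.points[self.best_index]

    @property
    def best_value(self) -> float:
        return self.values[self.best_index]

    @property
    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate(self.values)

    def to_json(self) -> dict:
        return {
            "points": self.points,
            "values": self.values,
            "best_point": self.best_point,
            "best_value": self.best_value,
            "seed": self.seed,
        }


def cv_objective(
    X: pd.DataFrame,
    y,
    task_type: str,
    params: dict,
    cv_folds: int = 5,
    seed: int = 0,
) -> float:
    """Minimized CV objective: RMSE (regression) or 1 - AUC."""
    if task_type == "classification":
        cv = StratifiedKFold(cv_folds, shuffle=True, random_state=seed)
        scoring = "roc_auc"
    else:
        cv = KFold(cv_folds, shuffle=True, random_state=seed)
        scoring = "neg_root_mean_squared_error"
    model = make_gbdt(task_type, params, seed)
    scores = cross_val_score(model, X, np.asarray(y), cv=cv, scoring=scoring, n_jobs=1)
    if task_type == "classification":
        return float(1.0 - scores.mean())
    return float(-scores.mean())


def coarse_grid_search(
    X: pd.DataFrame,
    y,
    grid: dict[str, list],
    task_type: str = "regression",
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[dict, dict[str, list], OptimizationTrace]:
    """Evaluate every grid point once; return the best point, a shrunken
    per-axis sub-grid bracketing it (plus/minus one grid step), and the
    evaluation trace."""
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty grid")
    names = list(grid)
    trace = OptimizationTrace(seed=seed)
    from itertools import product

    for combo in product(*(grid[n] for n in names)):
        point = dict(zip(names, combo))
        trace.record(point, cv_objective(X, y, task_type, point, cv_folds, seed))
    best = trace.best_point
    region = {}
    for n in names:
        axis = list(grid[n])
        i = axis.index(best[n])
        region[n] = axis[max(0, i - 1) : i + 2]
    return best, region, trace


def _expected_improvement(mu, sigma, best):
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (best - mu) / sigma
        ei = (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)
    return np.where(sigma > 0, ei, 0.0)


def minimize_function(
    objective: Callable[[dict], float],
    space: HyperparameterSpace,
    n_calls: int = 30,
    seed: int = 0,
    n_initial: int | None = None,
    n_candidates: int = 2048,
) -> OptimizationTrace:
    """Sequential GP/expected-improvement minimization of a black box.

    Deterministic under a fixed seed. ``n_initial`` seeded random points
    (default max(5, n_calls // 3)) are evaluated first; each subsequent
    point maximizes EI over a fresh pool of random candidates.
    """
    if not space.params:
        raise ValueError("empty hyperparameter space")
    if n_calls < 5:
        raise ValueError("n_calls must be >= 5")
    rng = np.random.default_rng(seed)
    if n_initial is None:
        n_initial = max(5, n_calls // 3)
    n_initial = min(n_initial, n_calls)
    trace = OptimizationTrace(seed=seed)
    for _ in range(n_initial):
        point = space.sample(rng)
        trace.record(point, objective(point))
    kernel = Matern(length_scale=0.3 * np.ones(len(space.params)), nu=2.5)
    for _ in range(n_calls - n_initial):
        Xobs = np.vstack([space.encode(p) for p in trace.points])
        yobs = np.asarray(trace.values)
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-6,
            normalize_y=True,
            random_state=int(rng.integers(2**31)),
        )
        gp.fit(Xobs, yobs)
        candidates = [space.sample(rng) for _ in range(n_candidates)]
        Xc = np.vstack([space.encode(p) for p in candidates])
        mu, sigma = gp.predict(Xc, return_std=True)
        ei = _expected_improvement(mu, sigma, yobs.min())
        point = candidates[int(np.argmax(ei))]
        trace.record(point, objective(point))
    return trace


def bayesian_optimize(
    X: pd.DataFrame,
    y,
    space: HyperparameterSpace = DEFAULT_SPACE,
    n_calls: int = 30,
    cv_folds: int = 5,
    seed: int = 0,
    task_type: str = "regression",
) -> OptimizationTrace:
    """Bayesian optimization of the GBDT CV objective over ``space``."""
    X = validate_matrix(X)

    def objective(point: dict) -> float:
        return cv_objective(X, y, task_type, point, cv_folds, seed)

    return minimize_function(objective, space, n_calls=n_calls, seed=seed)


def attach_embeddings(X_selected: pd.DataFrame, E: pd.DataFrame) -> pd.DataFrame:
    """Concatenate Mol2Vec columns after the selected descriptors.

    Used only at the optimization stage; earlier selection artifacts are
    untouched, which is what makes the GBFS and GBFS-Mol2Vec workflows
    share an identical selection prefix.
    """
    X_selected = pd.DataFrame(X_selected)
    E = pd.DataFrame(E)
    if E.shape[1] == 0:
        return X_selected
    if len(X_selected) != len(E):
        raise ValueError("row mismatch between descriptors and embeddings")
    clash = set(X_selected.columns) & set(E.columns)
    if clash:
        raise ValueError(f"embedding column name collision: {sorted(clash)}")
    E = E.set_axis(X_selected.index, axis=0)
    return pd.concat([X_selected, E], axis=1)


class FittedModel:
    """Final GBDT bound to an exact, ordered feature-name contract."""

    def __init__(self, model, feature_names: list[str], task_type: str, meta: dict):
        self._model = model
        self.feature_names = list(feature_names)
        self.task_type = task_type
        self.meta = meta

    def _align(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        missing = [c for c in self.feature_names if c not in X.columns]
        extra = [c for c in X.columns if c not in self.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature schema mismatch: missing={missing[:5]} extra={extra[:5]}"
            )
        return X[self.feature_names]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self._model.predict(self._align(X))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        if self.task_type != "classification":
            raise ValueError("probabilities only defined for classification")
        return self._model.predict_proba(self._align(X))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self._model.booster_.save_model(str(directory / "model.txt"))
        (directory / "model_meta.json").write_text(
            json.dumps(
                {
                    "feature_names": self.feature_names,
                    "task_type": self.task_type,
                    "meta": self.meta,
                }
            )
        )

    @classmethod
    def load(cls, directory: str | Path) -> "FittedModel":
        import lightgbm

        directory = Path(directory)
        meta = json.loads((directory / "model_meta.json").read_text())
        booster = lightgbm.Booster(model_file=str(directory / "model.txt"))

        class _BoosterAdapter:
            def __init__(self, b, task):
                self.booster_ = b
                self._task = task

            def predict(self, X):
                raw = self.booster_.predict(X)
                if self._task == "classification":
                    return (raw >= 0.5).astype(int)
                return raw

            def predict_proba(self, X):
                raw = self.booster_.predict(X)
                return np.column_stack([1 - raw, raw])

        return cls(
            _BoosterAdapter(booster, meta["task_type"]),
            meta["feature_names"],
            meta["task_type"],
            meta["meta"],
        )


def train_final_model(
    X: pd.DataFrame,
    y,
    task_type: str = "regression",
    best_point: dict | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit the final GBDT on the full training partition only."""
    X = validate_matrix(X)
    y = np.asarray(y)
    if task_type == "regression" and np.all(y == y[0]):
        import warnings

        warnings.warn("constant target: model will predict a constant")
    model = make_gbdt(task_type, best_point, seed)
    model.fit(X, y)
    return FittedModel(
        model,
        list(X.columns),
        task_type,
        meta={"seed": seed, "hyperparameters": best_point or {}},
    )
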