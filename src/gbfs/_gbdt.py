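"""Shared gradient-boosted decision tree (LightGBM) helpers.

A single place defines the default GBDT settings used by gain ranking,
subset curves, RFE and the final model, and extracts per-feature total
gain (objective loss reduction summed over all splits on the feature).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier, LGBMRegressor

#: defaults used by the selection stages (not the optimized final model)
DEFAULT_GBDT_PARAMS = {
    "n_estimators": 500,
    "learning_rate": 0.05,
    "num_leaves": 31,
    "min_child_samples": 5,
}

_FIXED = {"verbose": -1, "n_jobs": 1, "deterministic": True, "force_row_wise": True}


def make_gbdt(task_type: str, params: dict | None = None, seed: int = 0):
    """Build an unfitted LightGBM model for the given task."""
    merged = {**DEFAULT_GBDT_PARAMS, **(params or {}), **_FIXED}
    merged["random_state"] = seed
    if task_type == "classification":
        return LGBMClassifier(**merged)
    return LGBMRegressor(**merged)


def validate_matrix(X: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(X)
    if not np.isfinite(X.to_numpy(dtype=float)).all():
        raise ValueError("feature matrix contains non-finite values")
    if X.columns.duplicated().any():
        raise ValueError("feature matrix has duplicate column names")
    return X


def feature_gain(model) -> np.ndarray:
    """Total gain per feature from a fitted LightGBM model."""
    return model.booster_.feature_importance(importance_type="gain")
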