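"""Evaluation metrics for regression and classification tasks.

Regression: MAE, MSE, RMSE, Pearson's r and the coefficient of
determination R^2 defined as the square of Pearson's r (so R^2 here
measures linear association between prediction and truth, not explained
variance relative to the mean). Classification: accuracy, precision,
recall, F1 from confusion counts, and AUC-ROC computed as the
Mann-Whitney statistic P(score_pos > score_neg) + 0.5 P(tie).

Degenerate cases (0/0 precision, single-class AUC input) follow the
documented conventions below rather than raising, except where a value
is genuinely undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


def _check_pair(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty prediction set")
    return y_true, y_pred


def mae(y_true, y_pred) -> float:
    """Mean absolute error."""
    y, p = _check_pair(y_true, y_pred)
    return float(np.mean(np.abs(y - p)))


def mse(y_true, y_pred) -> float:
    """Mean squared error."""
    y, p = _check_pair(y_true, y_pred)
    return float(np.mean((y - p) ** 2))


def rmse(y_true, y_pred) -> float:
    """Root mean squared error."""
    return float(np.sqrt(mse(y_true, y_pred)))


def pearson_r(y_true, y_pred) -> float:
    """Pearson correlation coefficient (population-variance convention).

    r is invariant to the 1/N vs 1/(N-1) choice; the population form
    mirrors the covariance/variance definition used throughout.
    """
    y, p = _check_pair(y_true, y_pred)
    yc, pc = y - y.mean(), p - p.mean()
    denom = np.sqrt(np.mean(yc**2) * np.mean(pc**2))
    if denom == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.mean(yc * pc) / denom)


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination as the square of Pearson's r."""
    return pearson_r(y_true, y_pred) ** 2


@dataclass
class ConfusionCounts:
    """True/false positive/negative counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y = np.asarray(y_true, dtype=int)
        p = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y == 1) & (p == 1))),
            tn=int(np.sum((y == 0) & (p == 0))),
            fp=int(np.sum((y == 0) & (p == 1))),
            fn=int(np.sum((y == 1) & (p == 0))),
        )


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy, precision, recall and F1 from confusion counts.

    0/0 ratios are reported as 0.0 with the corresponding flag listed in
    the ``degenerate`` entry.
    """
    degenerate = []
    accuracy = (counts.tp + counts.tn) / counts.n if counts.n else 0.0
    if counts.tp + counts.fp == 0:
        precision, flag = 0.0, "precision"
        degenerate.append(flag)
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall = 0.0
        degenerate.append("recall")
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f1 = 0.0
        degenerate.append("f1")
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": float(accuracy),
        "precision": float(precision),
        "recall": float(recall),
        "f1": float(f1),
        "degenerate": degenerate,
    }


def auc_roc(y_true, scores) -> float:
    """AUC-ROC via the rank (Mann-Whitney) formulation, tie-aware."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def regression_report(y_true, y_pred) -> dict:
    return {
        "n": int(np.asarray(y_true).size),
        "mae": mae(y_true, y_pred),
        "mse": mse(y_true, y_pred),
        "rmse": rmse(y_true, y_pred),
        "r": pearson_r(y_true, y_pred),
        "r2": r_squared(y_true, y_pred),
    }


def multitask_mean(metric_fn, Y_true, Y_score) -> float:
    """Unweighted mean of a metric over tasks, skipping missing labels.

    ``Y_true`` and ``Y_score`` are (n_samples, n_tasks) arrays; NaN in
    ``Y_true`` marks a missing label for that molecule/task pair.
    """
    Y_true = np.asarray(Y_true, dtype=float)
    Y_score = np.asarray(Y_score, dtype=float)
    vals = []
    for t in range(Y_true.shape[1]):
        mask = ~np.isnan(Y_true[:, t])
        if mask.sum() == 0:
            continue
        vals.append(metric_fn(Y_true[mask, t], Y_score[mask, t]))
    if not vals:
        raise ValueError("no task with observed labels")
    return float(np.mean(vals))
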