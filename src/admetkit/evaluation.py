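"""Model quality metrics.

Regression: R^2 = 1 - sum((yhat_i - y_i)^2) / sum((y_i - ybar)^2) and
RMSE = sqrt(sum((y_i - yhat_i)^2) / N), where ybar is always the mean of the
TRAINING-set experimental values — also for test-set R^2_T, which is a
deliberate contract of this package. Q^2 / RMSE_cv use pooled out-of-fold
predictions from k-fold cross-validation.

Classification: ACC, SP = TN/(TN+FP), SE = TP/(TP+FN), AUC via the
Mann-Whitney rank statistic (ties count 1/2), and Cohen's kappa.

Fold error: fold = 1 + |yhat - y| / y, with within-2-fold / within-3-fold
success rates and the average fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is degenerate."""


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class ClassificationEval:
    ACC: float
    SP: float
    SE: float
    AUC: float
    kappa: float
    counts: ConfusionCounts | None = None


@dataclass
class RegressionEval:
    R2_F: float | None = None
    RMSE_F: float | None = None
    Q2: float | None = None
    RMSE_cv: float | None = None
    R2_T: float | None = None
    RMSE_T: float | None = None


@dataclass
class FoldErrorReport:
    folds: np.ndarray
    within_2fold: float
    within_3fold: float
    average_fold: float


def regression_metrics(
    y_true: Sequence[float],
    y_pred: Sequence[float],
    ybar_reference: float | None = None,
) -> tuple[float, float]:
    """Return (R^2, RMSE) against the training-set mean *ybar_reference*
    (defaults to the mean of *y_true* when evaluating on the training set
    itself)."""
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y.size < 2:
        raise ValueError("need n >= 2 for R^2")
    ybar = float(np.mean(y)) if ybar_reference is None else float(ybar_reference)
    ss_res = float(np.sum((yhat - y) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: all observed values equal the reference mean")
    r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return r2, rmse


def auc_score(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve by the rank statistic; ties contribute 1/2."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined for single-class y_true")
    ranks = rankdata(s)  # average ranks handle ties with the 1/2 convention
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_metrics(
    y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> ClassificationEval:
    """ACC/SP/SE/AUC/kappa at the given probability threshold."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("y_true must be binary 0/1")
    pred = (s >= threshold).astype(float)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    counts = ConfusionCounts(tp, fp, tn, fn)
    acc = (tp + tn) / counts.n
    if tp + fn == 0 or tn + fp == 0:
        raise UndefinedMetricError("SE or SP undefined for single-class y_true")
    se = tp / (tp + fn)
    sp = tn / (tn + fp)
    auc = auc_score(y, s)
    kappa = cohens_kappa(y, pred)
    return ClassificationEval(ACC=acc, SP=sp, SE=se, AUC=auc, kappa=kappa, counts=counts)


def cohens_kappa(y_true: Sequence[int], y_pred_labels: Sequence[int]) -> float:
    """kappa = (p_o - p_e) / (1 - p_e), chance agreement from marginals."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred_labels, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch")
    n = y.size
    p_o = float((y == p).mean())
    p_e = float(
        ((y == 1).mean() * (p == 1).mean()) + ((y == 0).mean() * (p == 0).mean())
    )
    if p_e == 1.0:
        warnings.warn("both raters constant and equal: kappa defined as 0")
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def fold_error_rates(
    y_true: Sequence[float], y_pred: Sequence[float], thresholds: tuple[float, float] = (2.0, 3.0)
) -> FoldErrorReport:
    """Per-sample fold = 1 + |yhat - y| / y and the within-k-fold rates."""
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if np.any(y == 0):
        raise ValueError("fold error undefined at zero truth")
    if np.any(y < 0):
        raise ValueError("fold error requires strictly positive y_true")
    folds = 1.0 + np.abs(yhat - y) / y
    lo, hi = thresholds
    return FoldErrorReport(
        folds=folds,
        within_2fold=float((folds <= lo).mean()),
        within_3fold=float((folds <= hi).mean()),
        average_fold=float(folds.mean()),
    )


def make_folds(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffled round-robin fold assignment; fold sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("k must be <= n")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [order[i::k] for i in range(k)]


def cross_validate(dataset, config, k: int = 5, seed: int = 0):
    """k-fold CV of a model configuration.

    Regression returns ``(Q2, RMSE_cv)`` computed from pooled out-of-fold
    predictions against the full training-set mean; classification returns a
    :class:`ClassificationEval` on pooled out-of-fold probabilities.
    """
    from . import modeling  # local import: modeling depends on this module

    n = dataset.n
    folds = make_folds(n, k, seed)
    ids = np.array(dataset.features.row_ids)
    oof = np.full(n, np.nan)
    for fold_idx in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold_idx] = False
        train = dataset.subset(list(ids[mask]))
        model = modeling.train(train, config)
        preds = modeling.predict(model, dataset.features.subset_rows(list(ids[fold_idx])))
        oof[fold_idx] = preds["probability"] if dataset.task == "classification" else preds["value"]
    if dataset.task == "regression":
        ybar = float(np.mean(dataset.y))
        q2, rmse_cv = regression_metrics(dataset.y, oof, ybar_reference=ybar)
        return q2, rmse_cv
    return classification_metrics(dataset.y, oof)
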