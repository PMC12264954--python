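"""Evaluation metrics for the AC classification and DTI regression tasks.

Classification (activity cliffs are the positive, minority class):
precision, recall, F1, Matthews correlation coefficient, and balanced
accuracy, all from a standard confusion table.

Regression: micro-averaged RMSE pools all predictions regardless of target,

    RMSE_micro = sqrt( sum_t sum_i (y_ti - yhat_ti)^2 / sum_t n_t ),

while macro-averaged RMSE gives every target equal weight,

    RMSE_macro = (1/T) sum_t sqrt( (1/n_t) sum_i (y_ti - yhat_ti)^2 ).

Zero-denominator conventions (precision or recall with an empty
denominator -> 0 with a warning; MCC with a zero denominator factor -> 0)
follow common practice and are logged so they are auditable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Task-appropriate subset of metrics; unused entries stay None."""

    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    mcc: float | None = None
    balanced_accuracy: float | None = None
    rmse_micro: float | None = None
    rmse_macro: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def confusion(true_labels, predicted, threshold: float = 0.5) -> ConfusionCounts:
    """Binarize probabilities (p >= threshold -> positive) and count outcomes."""
    y = np.asarray(true_labels).astype(int)
    p = np.asarray(predicted, dtype=float)
    if y.shape != p.shape:
        raise ValueError("true and predicted lengths differ")
    if y.size == 0:
        raise ValueError("empty prediction set")
    yhat = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
    )


def precision_recall_f1(c: ConfusionCounts) -> tuple[float, float, float]:
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined (no predicted positives); returning 0")
        precision = 0.0
    else:
        precision = c.tp / (c.tp + c.fp)
    if c.tp + c.fn == 0:
        warnings.warn("recall undefined (no actual positives); returning 0")
        recall = 0.0
    else:
        recall = c.tp / (c.tp + c.fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    denom = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if denom == 0:
        return 0.0
    num = c.tp * c.tn - c.fp * c.fn
    return num / math.sqrt(denom)


def balanced_accuracy(c: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity; undefined if a class is absent."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("balanced accuracy undefined: a class is absent")
    return 0.5 * (c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp))


def _check_prediction_set(target_ids, y_true, y_pred):
    t = np.asarray(target_ids)
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if not (t.shape == y.shape == yhat.shape):
        raise ValueError("target_ids, y_true, y_pred must have equal lengths")
    if y.size == 0:
        raise ValueError("empty prediction set")
    return t, y, yhat


def rmse_micro(target_ids, y_true, y_pred) -> float:
    """Pooled RMSE over all samples of all targets."""
    _, y, yhat = _check_prediction_set(target_ids, y_true, y_pred)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def rmse_macro(target_ids, y_true, y_pred) -> float:
    """Mean over targets of the per-target RMSE."""
    t, y, yhat = _check_prediction_set(target_ids, y_true, y_pred)
    sq = (y - yhat) ** 2
    df = pd.DataFrame({"target": t, "sq": sq})
    per_target = df.groupby("target")["sq"].mean().pow(0.5)
    return float(per_target.mean())


def per_target_rmse(target_ids, y_true, y_pred) -> pd.Series:
    """Per-target RMSE table (index: target_id)."""
    t, y, yhat = _check_prediction_set(target_ids, y_true, y_pred)
    df = pd.DataFrame({"target": t, "sq": (y - yhat) ** 2})
    return df.groupby("target")["sq"].mean().pow(0.5).rename("rmse")


def classification_report(true_labels, predicted,
                          threshold: float = 0.5) -> MetricReport:
    c = confusion(true_labels, predicted, threshold)
    p, r, f1 = precision_recall_f1(c)
    return MetricReport(precision=p, recall=r, f1=f1, mcc=mcc(c),
                        balanced_accuracy=balanced_accuracy(c))


def regression_report(target_ids, y_true, y_pred) -> MetricReport:
    return MetricReport(rmse_micro=rmse_micro(target_ids, y_true, y_pred),
                        rmse_macro=rmse_macro(target_ids, y_true, y_pred))
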