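"""Scoring metrics for labeled pair sets.

AUC is computed by the Mann-Whitney rank statistic with mid-rank tie
handling (equivalent to trapezoidal ROC integration; the test suite pins
that equivalence). AUPR follows the average-precision convention (step-wise
precision-recall summation, no interpolation). The count-based metrics use a
fixed decision threshold with the >= convention for ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

__all__ = ["MetricReport", "confusion_counts", "auc_score", "aupr_score",
           "compute_metrics"]


@dataclass
class MetricReport:
    """AUC, AUPR and threshold-based classification metrics for one pair set."""

    auc: float
    aupr: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float = 0.5

    def to_json(self) -> str:
        return json.dumps({k: round(v, 6) for k, v in self.__dict__.items()},
                          sort_keys=True)

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _check(labels, probs):
    labels = np.asarray(labels, dtype=np.float64).ravel()
    probs = np.asarray(probs, dtype=np.float64).ravel()
    if labels.shape != probs.shape:
        raise ValueError(f"length mismatch: {labels.size} labels vs {probs.size} scores")
    return labels, probs


def confusion_counts(labels, probs, threshold: float = 0.5):
    """(TP, FP, TN, FN) with prediction = 1 iff prob >= threshold."""
    labels, probs = _check(labels, probs)
    pred = probs >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, fp, tn, fn


def auc_score(labels, probs) -> float:
    """Area under the ROC curve via the rank statistic (mid-rank ties)."""
    labels, probs = _check(labels, probs)
    n_pos = int(np.sum(labels == 1))
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(probs)  # average (mid) ranks
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr_score(labels, probs) -> float:
    """Area under the precision-recall curve (average-precision convention)."""
    labels, probs = _check(labels, probs)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUPR requires both classes")
    return float(average_precision_score(labels, probs))


def compute_metrics(labels, probs, threshold: float = 0.5) -> MetricReport:
    """Full metric report for a scored pair set.

    Precision and F1 fall back to 0 when no positive predictions (or no
    positive labels) make them undefined.
    """
    tp, fp, tn, fn = confusion_counts(labels, probs, threshold)
    total = tp + fp + tn + fn
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return MetricReport(
        auc=auc_score(labels, probs),
        aupr=aupr_score(labels, probs),
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        threshold=threshold,
    )
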