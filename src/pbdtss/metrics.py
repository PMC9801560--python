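"""Imbalance-aware evaluation: sensitivity, specificity, G-mean, ROC, auROC.

TSS benchmarks are heavily imbalanced (about ten decoy windows per true site),
so plain accuracy is uninformative.  The thresholded summary used here is the
geometric mean of sensitivity and specificity; the threshold-free summary is
the area under the ROC curve, with tied scores grouped into a single sweep
step so that the area equals the Mann-Whitney pairwise statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


class UndefinedMetricError(ValueError):
    """A metric is requested for data where it is undefined (empty class)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "FP", "TN", "FN"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")


def counts_at_threshold(scores, labels, threshold: float = 0.0) -> ConfusionCounts:
    """Confusion counts predicting positive when score > threshold."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, float)
    pred = s > threshold
    pos = y > 0
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)), FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)), FN=int(np.sum(~pred & pos)))


def sensitivity(counts: ConfusionCounts) -> float:
    if counts.TP + counts.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive instances")
    return counts.TP / (counts.TP + counts.FN)


def specificity(counts: ConfusionCounts) -> float:
    if counts.TN + counts.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative instances")
    return counts.TN / (counts.TN + counts.FP)


def gmean(counts: ConfusionCounts) -> float:
    """G-mean = sqrt(Sn * Sp), robust to class imbalance."""
    return math.sqrt(sensitivity(counts) * specificity(counts))


@dataclass
class ROCResult:
    """ROC curve points (FP rate, TP rate) and the trapezoidal area under it."""

    points: np.ndarray
    auroc: float

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (FPR, TPR) pairs")
        if not (0.0 <= self.auroc <= 1.0):
            raise ValueError("auroc must lie in [0, 1]")


def roc_auroc(scores, labels) -> ROCResult:
    """ROC curve from a threshold sweep over the scores, ties grouped.

    Labels are -1/+1 (anything > 0 counts as positive); both classes must be
    present and all scores finite.
    """
    s = np.asarray(scores, float)
    y = (np.asarray(labels, float) > 0).astype(int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be aligned one-dimensional arrays")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.min() == y.max():
        raise UndefinedMetricError("ROC undefined: only one class present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return ROCResult(points=np.column_stack([fpr, tpr]), auroc=float(_sk_auc(fpr, tpr)))


def ci95(values: Sequence[float]) -> tuple[float, float]:
    """Mean and normal-approximation 95% halfwidth (1.96 sd / sqrt(n)) of replicates."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates for a confidence interval")
    return float(v.mean()), float(1.96 * v.std(ddof=1) / math.sqrt(v.size))
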