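"""Binary classification metrics: confusion counts, accuracy/precision/recall/F1,
rank-based AUC, incremental AUC, and paired comparison of iAUC curves.

Undefined ratios (empty denominators) are reported as NaN sentinels and
excluded from aggregation by the caller.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float = float("nan")


def confusion_counts(predictions: Sequence[int],
                     labels: Sequence[int]) -> ConfusionCounts:
    """Confusion counts for binary predictions vs labels (positives > 0)."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape:
        raise ValidationError(
            f"length mismatch: {pred.shape} predictions vs {lab.shape} labels")
    p = pred > 0
    t = lab > 0
    return ConfusionCounts(
        tp=int(np.sum(p & t)), fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)), fn=int(np.sum(~p & t)))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(c: ConfusionCounts, auc: float = float("nan")) -> MetricSet:
    """Accuracy, precision, recall and F1 from confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); F1 = 2 P R/(P+R) = 2 TP/(2 TP+FP+FN).
    """
    return MetricSet(
        accuracy=_ratio(c.tp + c.tn, c.total),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        auc=auc,
    )


def auc_rank(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (ties 1/2).

    The Mann-Whitney formulation: (sum of positive ranks - n_pos(n_pos+1)/2)
    / (n_pos n_neg), with midranks for ties.  NaN if either class is absent.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels) > 0
    if s.shape != y.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(s)
    u = float(ranks[y].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def compute_iauc(auc_by_interval: Sequence[float]) -> np.ndarray:
    """Successive AUC differences over the configured interval grid.

    iAUC at the first (zero) interval is exactly 0; thereafter
    iAUC(k_i) = AUC(k_i) - AUC(k_{i-1}).  A non-finite entry is an error.
    """
    a = np.asarray(auc_by_interval, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValidationError("AUC must be defined at every interval")
    out = np.zeros_like(a)
    out[1:] = np.diff(a)
    return out


def compare_iauc_curves(curve_a: Sequence[float], curve_b: Sequence[float],
                        drop_first: bool = True) -> tuple[float, float]:
    """Paired two-sided t-test on per-interval iAUC differences.

    ``drop_first`` removes the structural-zero baseline entries.  Degenerate
    variance sentinels: identical curves give (0.0, 1.0); a constant nonzero
    difference gives (+/-inf, 0.0).
    """
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("iAUC curves must have equal length")
    if drop_first:
        a, b = a[1:], b[1:]
    if a.size < 2:
        raise ValidationError("need at least 2 paired iAUC values")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
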