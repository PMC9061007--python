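"""Classification evaluation: confusion-matrix metrics, ROC/AUC, paired
t-tests and Holm-Bonferroni correction.

The symptomatic class (label 1) is the positive class throughout.  The five
metrics are

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall),  recall = sensitivity

A metric whose denominator is zero is reported as *undefined* (None) and
flagged, never silently as 0 — averaging a spurious 0 over folds would
deflate the summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "RocResult",
    "PairedTResult",
    "confusion",
    "metrics",
    "roc_auc",
    "paired_t_test",
    "holm_bonferroni",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The five derived metrics; ``None`` marks an undefined (0/0) value."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    undefined: frozenset = frozenset()

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class PairedTResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def confusion(labels, predictions, positive: int = 1) -> ConfusionCounts:
    """Count TP/FP/TN/FN with the symptomatic class as positive."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"labels and predictions differ in length: {labels.shape} vs {predictions.shape}"
        )
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    pos = labels == positive
    pred_pos = predictions == positive
    return ConfusionCounts(
        tp=int((pos & pred_pos).sum()),
        fp=int((~pos & pred_pos).sum()),
        tn=int((~pos & ~pred_pos).sum()),
        fn=int((pos & ~pred_pos).sum()),
    )


def _ratio(num: int, den: int):
    return None if den == 0 else num / den


def metrics(counts: ConfusionCounts) -> MetricSet:
    """The five metrics from confusion counts, with the undefined policy."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from zero evaluated subjects")
    acc = (counts.tp + counts.tn) / counts.total
    sen = _ratio(counts.tp, counts.tp + counts.fn)
    spe = _ratio(counts.tn, counts.tn + counts.fp)
    pre = _ratio(counts.tp, counts.tp + counts.fp)
    if sen is None or pre is None or (pre + sen) == 0:
        f1 = None
    else:
        f1 = 2 * pre * sen / (pre + sen)
    undefined = frozenset(
        name for name, v in zip(METRIC_NAMES, (acc, sen, spe, pre, f1)) if v is None
    )
    return MetricSet(acc, sen, spe, pre, f1, undefined)


def roc_auc(labels, scores) -> RocResult:
    """ROC curve by threshold sweep plus trapezoidal AUC.

    ``scores`` are real-valued confidences for the positive (symptomatic)
    class; both classes must be present.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present in the labels")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds, fpr, tpr, auc)


def paired_t_test(metric_series_a, metric_series_b) -> PairedTResult:
    """Two-sided paired t-test on per-fold metric series.

    A zero-variance difference series is degenerate: the p-value is flagged
    and reported as 1 when the series are identical and 0 when they differ
    by a nonzero constant.
    """
    a = np.asarray(metric_series_a, dtype=float)
    b = np.asarray(metric_series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        mean = float(d.mean())
        return PairedTResult(
            statistic=0.0 if mean == 0 else math.copysign(math.inf, mean),
            p_value=1.0 if mean == 0 else 0.0,
            degenerate=True,
        )
    res = stats.ttest_rel(a, b)
    return PairedTResult(float(res.statistic), float(res.pvalue), False)


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down correction: the k-th smallest p is multiplied by
    (N - k + 1), corrected values are made monotone nondecreasing along the
    sorted order and capped at 1; returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]
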