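"""Confusion-matrix accounting and the four performance indicators.

Melanoma is the positive class throughout: TP counts melanoma images
correctly flagged as melanoma, TN common nevi correctly cleared.  The four
indicators are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    DSC         = 2 TP / (2 TP + FP + FN)

An indicator with a zero denominator raises :class:`UndefinedMetricError`
rather than silently returning 0 — a silent zero would corrupt the fusion
weights derived from validation accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from ._util import round_half_away


class UndefinedMetricError(ZeroDivisionError):
    """An indicator's denominator is zero for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.total < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceReport:
    counts: ConfusionCounts
    accuracy: float
    specificity: float
    sensitivity: float
    dsc: float

    def as_dict(self) -> dict:
        return {
            "counts": {
                "tp": self.counts.tp,
                "tn": self.counts.tn,
                "fp": self.counts.fp,
                "fn": self.counts.fn,
            },
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "dsc": self.dsc,
        }


def confusion_counts(decisions, labels) -> ConfusionCounts:
    """Tally TP/TN/FP/FN from binary decisions vs true labels (melanoma=1)."""
    d = np.asarray(decisions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if d.shape != y.shape or d.ndim != 1:
        raise ValueError(f"decisions {d.shape} and labels {y.shape} must be equal-length vectors")
    if d.size < 1:
        raise ValueError("need at least one decision")
    return ConfusionCounts(
        tp=int(np.sum((d == 1) & (y == 1))),
        tn=int(np.sum((d == 0) & (y == 0))),
        fp=int(np.sum((d == 1) & (y == 0))),
        fn=int(np.sum((d == 0) & (y == 1))),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total < 1:
        raise UndefinedMetricError("accuracy undefined for empty counts")
    return (c.tp + c.tn) / c.total


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp < 1:
        raise UndefinedMetricError("specificity undefined without negatives")
    return c.tn / (c.tn + c.fp)


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn < 1:
        raise UndefinedMetricError("sensitivity undefined without positives")
    return c.tp / (c.tp + c.fn)


def dice_similarity(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom < 1:
        raise UndefinedMetricError("DSC undefined when 2TP+FP+FN = 0")
    return 2 * c.tp / denom


def performance_report(c: ConfusionCounts) -> PerformanceReport:
    """All four indicators in one report."""
    return PerformanceReport(
        counts=c,
        accuracy=accuracy(c),
        specificity=specificity(c),
        sensitivity=sensitivity(c),
        dsc=dice_similarity(c),
    )


def format_percent(fraction: float) -> str:
    """Render a fraction as a percentage with 2 decimals, half-away rounding.

    28/30 -> '93.33%'; the style used in the result tables.
    """
    return f"{round_half_away(fraction * 100.0, 2):.2f}%"


def roc_curve(scores, labels):
    """ROC points and trapezoid AUC for melanoma scores vs true labels.

    Returns ``(fpr, tpr, auc)`` with both coordinate arrays monotone
    non-decreasing over the swept thresholds.  Raises
    :class:`UndefinedMetricError` unless both classes are present.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("ROC undefined with a single class")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    return fpr, tpr, float(_skm.auc(fpr, tpr))
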