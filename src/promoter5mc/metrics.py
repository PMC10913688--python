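"""Confusion-matrix metrics and threshold-free curve summaries.

Sensitivity, specificity, accuracy and the Matthews correlation coefficient
are computed directly from the confusion counts:

    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)
    Acc = (TP + TN) / (TP + TN + FP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Any metric whose denominator is zero is reported as 0 so that reports stay
total. ROC-AUC uses midrank tie handling (equal to the probability that a
random positive outscores a random negative, ties counting half); PR-AUC is
the step-wise precision-recall area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ConfusionCounts", "MetricsReport", "confusion", "metrics_from_confusion",
    "roc_auc", "pr_auc", "f1_from_confusion", "mean_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_scores(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(f"labels {labels.shape} and scores {scores.shape} disagree")
    if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
        raise ValueError("scores must lie in [0, 1]")
    return labels, scores


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally counts with prediction = 1 iff score >= threshold."""
    labels, scores = _check_scores(labels, scores)
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def metrics_from_confusion(c: ConfusionCounts) -> tuple[float, float, float, float]:
    """(sn, sp, acc, mcc); zero-denominator metrics are 0 by convention."""
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    sn = _safe_div(c.tp, c.tp + c.fn)
    sp = _safe_div(c.tn, c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, math.sqrt(den)) if den > 0 else 0.0
    return sn, sp, acc, mcc


def f1_from_confusion(c: ConfusionCounts) -> float:
    return _safe_div(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def _check_both_classes(labels: np.ndarray, what: str) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError(f"{what} requires both classes to be present")


def roc_auc(labels, scores) -> float:
    labels, scores = _check_scores(labels, scores)
    _check_both_classes(labels, "ROC-AUC")
    return float(roc_auc_score(labels, scores))


def pr_auc(labels, scores) -> float:
    labels, scores = _check_scores(labels, scores)
    if not np.any(labels == 1):
        raise ValueError("PR-AUC requires at least one positive sample")
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class MetricsReport:
    """Sn/Sp/Acc/MCC at a threshold plus threshold-free AUCs and F1."""

    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    f1: float
    pr_auc: float
    threshold: float = 0.5

    @classmethod
    def from_scores(cls, labels, scores, threshold: float = 0.5) -> "MetricsReport":
        c = confusion(labels, scores, threshold)
        sn, sp, acc, mcc = metrics_from_confusion(c)
        return cls(sn=sn, sp=sp, acc=acc, mcc=mcc,
                   auc=roc_auc(labels, scores),
                   f1=f1_from_confusion(c),
                   pr_auc=pr_auc(labels, scores),
                   threshold=threshold)

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def __str__(self) -> str:
        return (f"Sn={self.sn:.4f} Sp={self.sp:.4f} Acc={self.acc:.4f} "
                f"MCC={self.mcc:.4f} AUC={self.auc:.4f} F1={self.f1:.4f} "
                f"PR-AUC={self.pr_auc:.4f} (threshold {self.threshold})")


def mean_report(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of each metric across fold reports."""
    if not reports:
        raise ValueError("no reports to average")
    fields = ("sn", "sp", "acc", "mcc", "auc", "f1", "pr_auc", "threshold")
    means = {f: float(np.mean([getattr(r, f) for r in reports])) for f in fields}
    return MetricsReport(**means)
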