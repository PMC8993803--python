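"""Confusion-count bookkeeping and the six evaluation metrics.

For a multiclass task every class is tallied one-vs-rest (TP, TN, FP, FN),
and the binary formulas

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)
    precision   = TP / (TP + FP)
    recall      = TP / (TP + FN)
    F1          = 2 * precision * recall / (precision + recall)

are applied under an explicit averaging policy. The default is **micro**
(pool the counts across classes, then apply the formula); **macro**
(average the per-class values) is available. For single-label multiclass
data micro precision, recall, F1 and accuracy coincide — a mathematical
identity this module uses as a self-test. Note that micro specificity pools
one-vs-rest true negatives, which grows with the number of classes; it is
reported as defined, not corrected.

Degenerate denominators yield 0 with a logged warning rather than NaN.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "accuracy",
    "specificity",
    "sensitivity",
    "precision",
    "recall",
    "f1",
    "metrics_report",
]

#: Fixed emission order of the report columns.
REPORT_KEYS = ("accuracy", "specificity", "precision", "f1", "recall", "sensitivity")


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest tallies; arrays indexed by class position."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    class_set: tuple[str, ...]

    def __post_init__(self) -> None:
        for arr in (self.tp, self.tn, self.fp, self.fn):
            if arr.shape != (len(self.class_set),) or (arr < 0).any():
                raise ValueError("counts must be one non-negative entry per class")
        totals = self.tp + self.tn + self.fp + self.fn
        if len(set(totals.tolist())) > 1:
            raise ValueError("per-class totals must all equal the sample count")

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    @property
    def total(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])

    def pooled(self) -> tuple[int, int, int, int]:
        """Micro-averaged (TP, TN, FP, FN) summed over classes."""
        return int(self.tp.sum()), int(self.tn.sum()), int(self.fp.sum()), int(self.fn.sum())


def confusion(y_true, y_pred, class_set) -> ConfusionCounts:
    """One-vs-rest confusion tallies for every class."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred) or not y_true:
        raise ValueError("y_true and y_pred must be equal non-zero length")
    class_set = tuple(class_set)
    index = {c: i for i, c in enumerate(class_set)}
    for lab in set(y_true) | set(y_pred):
        if lab not in index:
            raise ValueError(f"label {lab!r} not in class set {class_set}")
    k = len(class_set)
    tp = np.zeros(k, dtype=int)
    tn = np.zeros(k, dtype=int)
    fp = np.zeros(k, dtype=int)
    fn = np.zeros(k, dtype=int)
    for t, p in zip(y_true, y_pred):
        ti, pi = index[t], index[p]
        for c in range(k):
            if ti == c and pi == c:
                tp[c] += 1
            elif ti == c:
                fn[c] += 1
            elif pi == c:
                fp[c] += 1
            else:
                tn[c] += 1
    return ConfusionCounts(tp, tn, fp, fn, class_set)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", what)
        return 0.0
    return num / den


Counts = "ConfusionCounts | tuple[int, int, int, int]"


def _dispatch(c, averaging: str, fn_binary) -> float:
    """Apply a binary formula under the averaging policy.

    A raw ``(TP, TN, FP, FN)`` tuple is treated as one binary count table
    and the printed formula applies directly. For a multiclass
    :class:`ConfusionCounts`, micro pools the one-vs-rest counts first and
    macro averages the per-class values.
    """
    if isinstance(c, tuple):
        return fn_binary(*(int(v) for v in c))
    if averaging == "micro":
        tp, tn, fp, fn_ = c.pooled()
        return fn_binary(tp, tn, fp, fn_)
    if averaging == "macro":
        return float(np.mean([
            fn_binary(int(c.tp[i]), int(c.tn[i]), int(c.fp[i]), int(c.fn[i]))
            for i in range(c.n_classes)
        ]))
    raise ValueError(f"unknown averaging {averaging!r}")


def accuracy(c, averaging: str = "micro") -> float:
    """(TP+TN)/(TP+TN+FP+FN) on a binary table; fraction of correctly
    classified samples (sum of per-class TP over the sample count) under
    micro averaging — the two coincide for binary data."""
    if isinstance(c, tuple):
        tp, tn, fp, fn_ = (int(v) for v in c)
        if tp + tn + fp + fn_ == 0:
            raise ValueError("accuracy undefined for zero samples")
        return (tp + tn) / (tp + tn + fp + fn_)
    if c.total == 0:
        raise ValueError("accuracy undefined for zero samples")
    if averaging == "micro":
        return float(c.tp.sum()) / c.total
    return _dispatch(c, averaging,
                     lambda tp, tn, fp, fn_: _safe_div(tp + tn, tp + tn + fp + fn_, "accuracy"))


def specificity(c, averaging: str = "micro") -> float:
    """TN/(TN+FP). Micro pools one-vs-rest negatives across classes (grows
    with class count, reported as defined)."""
    return _dispatch(c, averaging,
                     lambda tp, tn, fp, fn_: _safe_div(tn, tn + fp, "specificity"))


def sensitivity(c, averaging: str = "micro") -> float:
    """TP/(TP+FN) — the true-positive rate."""
    return _dispatch(c, averaging,
                     lambda tp, tn, fp, fn_: _safe_div(tp, tp + fn_, "sensitivity"))


def precision(c, averaging: str = "micro") -> float:
    """TP/(TP+FP)."""
    return _dispatch(c, averaging,
                     lambda tp, tn, fp, fn_: _safe_div(tp, tp + fp, "precision"))


def recall(c, averaging: str = "micro") -> float:
    """TP/(TP+FN); identical to sensitivity by definition."""
    return sensitivity(c, averaging)


def f1(c, averaging: str = "micro") -> float:
    """Harmonic mean of precision and recall."""
    def binary(tp, tn, fp, fn_):
        p = _safe_div(tp, tp + fp, "precision")
        r = _safe_div(tp, tp + fn_, "recall")
        return _safe_div(2 * p * r, p + r, "f1")

    return _dispatch(c, averaging, binary)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    specificity: float
    precision: float
    f1: float
    recall: float
    sensitivity: float
    averaging: str = "micro"

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in REPORT_KEYS}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({**self.as_dict(), "averaging": self.averaging}, fh, indent=2)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(REPORT_KEYS)
            w.writerow([f"{getattr(self, k):.6f}" for k in REPORT_KEYS])


def metrics_report(y_true, y_pred, class_set, averaging: str = "micro") -> MetricsReport:
    """Full six-metric report from raw label vectors."""
    c = confusion(y_true, y_pred, class_set)
    return MetricsReport(
        accuracy=accuracy(c, averaging),
        specificity=specificity(c, averaging),
        precision=precision(c, averaging),
        f1=f1(c, averaging),
        recall=recall(c, averaging),
        sensitivity=sensitivity(c, averaging),
        averaging=averaging,
    )
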