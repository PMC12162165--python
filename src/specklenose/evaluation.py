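"""Confusion matrices and classification metrics.

Multi-class results are collapsed one-vs-rest into (TP, TN, FP, FN)
counts, from which the standard scores follow:

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (recall)
    specificity = TN / (FP + TN)
    F1          = 2 * P * R / (P + R)

A metric whose denominator vanishes is flagged *undefined* rather than
silently coerced to 0 — coercion would inflate macro averages on absent
classes.  Multi-class summaries are unweighted (macro) means over the
defined per-class values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "BinaryCounts",
    "Metrics",
    "METRIC_NAMES",
    "confusion_matrix",
    "normalize_rows",
    "binary_counts",
    "metrics",
    "macro_metrics",
]

METRIC_NAMES = ("accuracy", "precision", "sensitivity", "specificity", "f1")


@dataclass
class ConfusionMatrix:
    """C x C counts; rows are true classes, columns predicted."""

    counts: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        C = len(self.class_order)
        if self.counts.shape != (C, C):
            raise ValueError("counts must be square and match class_order")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, class_order: Sequence[str]
) -> ConfusionMatrix:
    """Count matrix with ``counts[i, j] = #{true=class_i and pred=class_j}``."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {c: i for i, c in enumerate(class_order)}
    counts = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class_order: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=list(class_order))


def normalize_rows(m: ConfusionMatrix) -> tuple[np.ndarray, list[str]]:
    """Row-normalized matrix (each true class rescaled to 1.00 samples).

    Returns the float matrix and the list of class names whose row was
    all-zero (left as zeros, flagged instead of divided).
    """
    counts = m.counts.astype(np.float64)
    sums = counts.sum(axis=1, keepdims=True)
    zero_rows = [m.class_order[i] for i in range(len(m.class_order)) if sums[i, 0] == 0]
    safe = np.where(sums == 0, 1.0, sums)
    return counts / safe, zero_rows


@dataclass(frozen=True)
class BinaryCounts:
    """One-vs-rest collapse of a confusion matrix."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def binary_counts(m: ConfusionMatrix, positive_class: str) -> BinaryCounts:
    """TP/TN/FP/FN treating ``positive_class`` as positive."""
    if positive_class not in m.class_order:
        raise ValueError(f"unknown class {positive_class!r}")
    i = m.class_order.index(positive_class)
    counts = m.counts
    TP = int(counts[i, i])
    FN = int(counts[i, :].sum() - TP)
    FP = int(counts[:, i].sum() - TP)
    TN = int(counts.sum() - TP - FN - FP)
    return BinaryCounts(TP=TP, TN=TN, FP=FP, FN=FN)


@dataclass
class Metrics:
    """Score set; ``None`` marks an undefined (zero-denominator) metric."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def metrics(c: BinaryCounts) -> Metrics:
    """Scores from binary counts; zero denominators are flagged."""
    if c.n == 0:
        raise ValueError("metrics require at least one instance")
    precision = _ratio(c.TP, c.TP + c.FP)
    sensitivity = _ratio(c.TP, c.TP + c.FN)
    if precision is None or sensitivity is None or precision + sensitivity == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    result = Metrics(
        accuracy=(c.TP + c.TN) / c.n,
        precision=precision,
        sensitivity=sensitivity,
        specificity=_ratio(c.TN, c.FP + c.TN),
        f1=f1,
    )
    result.undefined = [k for k, v in result.as_dict().items() if v is None]
    return result


def macro_metrics(m: ConfusionMatrix) -> Metrics:
    """Unweighted mean of one-vs-rest metrics over the classes.

    Undefined per-class entries are skipped (and counted in
    ``undefined`` as ``"class:metric"`` markers); a metric undefined for
    every class stays ``None``.
    """
    if len(m.class_order) < 2:
        raise ValueError("macro metrics require at least 2 classes")
    per_class = {name: [] for name in METRIC_NAMES}
    skipped: list[str] = []
    for cls in m.class_order:
        scores = metrics(binary_counts(m, cls))
        for name in METRIC_NAMES:
            val = getattr(scores, name)
            if val is None:
                skipped.append(f"{cls}:{name}")
            else:
                per_class[name].append(val)
    values = {
        name: (float(np.mean(vals)) if vals else None)
        for name, vals in per_class.items()
    }
    result = Metrics(**values)  # type: ignore[arg-type]
    result.undefined = skipped + [k for k, v in result.as_dict().items() if v is None]
    return result


def metrics_table(m: ConfusionMatrix) -> pd.DataFrame:
    """Long-format metric table: per class plus the macro row."""
    rows = []
    for cls in m.class_order:
        scores = metrics(binary_counts(m, cls))
        for name, value in scores.as_dict().items():
            rows.append(dict(scope=cls, metric=name,
                             value=math.nan if value is None else value))
    macro = macro_metrics(m)
    for name, value in macro.as_dict().items():
        rows.append(dict(scope="macro", metric=name,
                         value=math.nan if value is None else value))
    return pd.DataFrame(rows)
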