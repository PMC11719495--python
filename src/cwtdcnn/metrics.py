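"""Confusion matrix and the five binary evaluation scores.

Epilepsy is the positive class: TP = segments correctly predicted
epileptic, TN = correctly predicted normal. The scores are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)          (recall on the epilepsy class)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

A score whose denominator is zero is reported as 0.0 with a warning (so
batch sweeps never crash); an all-zero confusion matrix is an error.
Fractions are kept at full precision internally and reported x100 to two
decimals in exported tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "score"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float

    def as_percentages(self, ndigits: int = 2) -> dict[str, float]:
        """Scores x100, rounded — the form used in results tables."""
        return {
            k: round(100.0 * v, ndigits)
            for k, v in (
                ("accuracy", self.accuracy),
                ("sensitivity", self.sensitivity),
                ("specificity", self.specificity),
                ("precision", self.precision),
                ("f1", self.f1),
            )
        }


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FP/FN/TN from equal-length binary vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be equal-length 1-D vectors")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary (0 = normal, 1 = epilepsy)")
    t = y_true.astype(bool)
    p = y_pred.astype(bool)
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} denominator is zero; reporting 0.0", stacklevel=3)
        return 0.0
    return num / den


def score(cm: ConfusionMatrix) -> MetricsReport:
    """The five scores of a confusion matrix (fractions in [0, 1])."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    if precision + sensitivity == 0:
        f1 = 0.0
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        f1=f1,
    )
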