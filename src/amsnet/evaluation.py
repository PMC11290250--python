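"""Confusion-matrix construction and per-class evaluation metrics.

All five metrics are reported as percentages rounded half-up to two
decimals, the convention used for clinical classifier reporting:

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)        (recall / true-positive rate)
    specificity = TN / (TN + FP)        (true-negative rate)
    F1          = 200 * TP / (2 TP + FP + FN)
    accuracy    = (TP + TN) / total

In the binary case swapping the designated positive class swaps sensitivity
with specificity and moves precision to the other class's row; accuracy is
invariant.  Zero-denominator ratios are reported as 0 with a degenerate
flag instead of raising, so tiny fixtures evaluate cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from fractions import Fraction

import numpy as np

from .backbone import AMSNet
from .synthetic import LABELS, LabeledSample

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion",
           "metrics_from_confusion", "evaluate"]


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "abnormal"

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The same predictions viewed with the other class as positive."""
        other = [c for c in LABELS if c != self.positive_class][0]
        return ConfusionMatrix(tp=self.tn, fp=self.fn, tn=self.tp,
                               fn=self.fp, positive_class=other)


@dataclass
class MetricsReport:
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    positive_class: str
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"positive_class": self.positive_class,
                "precision": self.precision, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "f1": self.f1,
                "accuracy": self.accuracy,
                "degenerate": list(self.degenerate)}


def confusion(predictions, truths, positive: str = "abnormal") -> ConfusionMatrix:
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("predictions and truths differ in length")
    labels = set(predictions) | set(truths)
    if not labels <= set(LABELS):
        raise ValueError(f"unknown labels: {sorted(labels - set(LABELS))}")
    if positive not in LABELS:
        raise ValueError(f"unknown positive class {positive!r}")
    tp = fp = tn = fn = 0
    for p, t in zip(predictions, truths):
        if p == positive:
            if t == positive:
                tp += 1
            else:
                fp += 1
        else:
            if t == positive:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn,
                           positive_class=positive)


def _pct(num: int, den: int, flags: list, name: str) -> float:
    """Exact ratio -> percentage, half-up rounded to 2 decimals."""
    if den == 0:
        flags.append(name)
        return 0.0
    frac = Fraction(100 * num, den)
    dec = Decimal(frac.numerator) / Decimal(frac.denominator)
    return float(dec.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    return MetricsReport(
        precision=_pct(cm.tp, cm.tp + cm.fp, flags, "precision"),
        sensitivity=_pct(cm.tp, cm.tp + cm.fn, flags, "sensitivity"),
        specificity=_pct(cm.tn, cm.tn + cm.fp, flags, "specificity"),
        f1=_pct(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, flags, "f1"),
        accuracy=_pct(cm.tp + cm.tn, cm.total, flags, "accuracy"),
        positive_class=cm.positive_class,
        degenerate=tuple(flags),
    )


def evaluate(model: AMSNet, samples: list[LabeledSample],
             batch_size: int = 16):
    """Deterministic inference + both per-class metric rows.

    Returns ``(reports, cm)`` where ``reports`` maps each class name to the
    MetricsReport with that class designated positive, and ``cm`` is the
    confusion matrix with 'abnormal' positive.
    """
    if not samples:
        raise ValueError("sample list must be non-empty")
    x = np.stack([s.image for s in samples])
    truths = [s.label for s in samples]
    preds = []
    for i in range(0, len(x), batch_size):
        logits = model.predict_logits(x[i:i + batch_size])
        preds.extend(LABELS[k] for k in logits.argmax(axis=1))
    cm = confusion(preds, truths, positive="abnormal")
    reports = {"abnormal": metrics_from_confusion(cm),
               "normal": metrics_from_confusion(cm.swapped())}
    return reports, cm
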