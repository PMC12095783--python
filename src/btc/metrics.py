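"""Confusion-matrix evaluation suite.

For an n-class confusion matrix C (rows = actual class, columns =
predicted class), each class c is scored one-vs-rest from

    TP = C[c, c]             FN = row c sum  - TP
    FP = column c sum - TP   TN = total - TP - FN - FP

with the five standard metrics::

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    specificity = TN / (TN + FP)
    sensitivity = TP / (TP + FN)          (recall)
    precision   = TP / (TP + FP)
    F1          = 2 * precision * recall / (precision + recall)

The "overall accuracy" of a report is the macro average (unweighted
mean) of the per-class accuracies; trace/total is reported separately
as the fold accuracy.  Zero-denominator metrics are reported as 0 with
a degenerate flag rather than raising.  Summaries round half-up to 4
decimal places.

A published reference confusion matrix for the three-class brain-tumor
problem (3,064 T1-CE MRI slices: meningioma, glioma, pituitary) ships
with the package as ``data/reference_confusion.csv`` and serves as a
worked example: running this module on it must reproduce the published
per-class metric table cell for cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_CLASS_ORDER = ("meningioma", "glioma", "pituitary")


def round4(x: float) -> float:
    """Round half-up to 4 decimal places (report formatting rule)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.0001"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """n x n nonnegative integer counts; rows actual, columns predicted."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.class_names = tuple(self.class_names)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if self.counts.shape[0] != len(self.class_names):
            raise ValueError("class_names length must match matrix size")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.class_names)


@dataclass
class ClassMetrics:
    """One-vs-rest counts and the five derived metrics for one class."""

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float = field(init=False)
    specificity: float = field(init=False)
    sensitivity: float = field(init=False)
    precision: float = field(init=False)
    f1: float = field(init=False)
    degenerate: list = field(default_factory=list)

    def __post_init__(self) -> None:
        def ratio(num: float, den: float, name: str) -> float:
            if den == 0:
                self.degenerate.append(name)
                return 0.0
            return num / den

        self.accuracy = ratio(self.tp + self.tn,
                              self.tp + self.tn + self.fp + self.fn, "accuracy")
        self.specificity = ratio(self.tn, self.tn + self.fp, "specificity")
        self.sensitivity = ratio(self.tp, self.tp + self.fn, "sensitivity")
        self.precision = ratio(self.tp, self.tp + self.fp, "precision")
        self.f1 = ratio(2 * self.precision * self.sensitivity,
                        self.precision + self.sensitivity, "f1")

    def as_dict(self, rounded: bool = False) -> dict:
        vals = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
        }
        if rounded:
            vals = {k: round4(v) for k, v in vals.items()}
        vals.update(tp=self.tp, tn=self.tn, fp=self.fp, fn=self.fn,
                    degenerate=list(self.degenerate))
        return vals


def confusion(
    actual, predicted, class_order: tuple[str, ...] | list[str]
) -> ConfusionMatrix:
    """Count matrix with counts[i, j] = #(actual = class i, predicted =
    class j); empty inputs yield an all-zero matrix with a warning."""
    from sklearn.metrics import confusion_matrix as sk_confusion

    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError("actual and predicted must have equal length")
    class_order = tuple(class_order)
    if actual.size == 0:
        warnings.warn("confusion: empty label sequences", stacklevel=2)
        n = len(class_order)
        return ConfusionMatrix(np.zeros((n, n), dtype=int), class_order)
    known = set(class_order)
    seen = set(actual.tolist()) | set(predicted.tolist())
    if not seen <= known:
        raise ValueError(f"unknown labels: {sorted(seen - known)}")
    counts = sk_confusion(actual, predicted, labels=list(class_order))
    return ConfusionMatrix(counts, class_order)


def one_vs_rest_counts(cm: ConfusionMatrix, c: int | str) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) of class ``c`` against the rest."""
    if isinstance(c, str):
        c = cm.class_names.index(c)
    tp = int(cm.counts[c, c])
    fn = int(cm.counts[c].sum() - tp)
    fp = int(cm.counts[:, c].sum() - tp)
    tn = cm.total - tp - fn - fp
    return tp, tn, fp, fn


def class_metrics(cm: ConfusionMatrix, c: int | str) -> ClassMetrics:
    """All five one-vs-rest metrics of class ``c``."""
    tp, tn, fp, fn = one_vs_rest_counts(cm, c)
    return ClassMetrics(tp=tp, tn=tn, fp=fp, fn=fn)


def macro_average(per_class: dict[str, ClassMetrics] | list[ClassMetrics]) -> dict:
    """Unweighted mean of each metric across classes."""
    metrics = list(per_class.values()) if isinstance(per_class, dict) else list(per_class)
    if not metrics:
        raise ValueError("need at least one class")
    return {
        key: float(np.mean([getattr(m, key) for m in metrics]))
        for key in ("accuracy", "sensitivity", "specificity", "precision", "f1")
    }


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified samples, trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return cm.trace / cm.total


@dataclass
class MetricReport:
    """Per-class metrics, macro averages, and the trace/total accuracy."""

    confusion: ConfusionMatrix
    per_class: dict[str, dict]
    macro: dict
    fold_accuracy: float

    def as_dict(self, rounded: bool = True) -> dict:
        rnd = round4 if rounded else (lambda v: v)
        return {
            "confusion": self.confusion.counts.tolist(),
            "class_order": list(self.confusion.class_names),
            "per_class": {
                name: {k: (rnd(v) if isinstance(v, float) else v)
                       for k, v in vals.items()}
                for name, vals in self.per_class.items()
            },
            "macro": {k: rnd(v) for k, v in self.macro.items()},
            "fold_accuracy": rnd(self.fold_accuracy),
            "n_correct": self.confusion.trace,
            "n_misclassified": self.confusion.total - self.confusion.trace,
        }


def evaluate_confusion(cm: ConfusionMatrix) -> MetricReport:
    """Full metric suite of one confusion matrix."""
    per_class_metrics = {name: class_metrics(cm, name) for name in cm.class_names}
    return MetricReport(
        confusion=cm,
        per_class={n: m.as_dict() for n, m in per_class_metrics.items()},
        macro=macro_average(per_class_metrics),
        fold_accuracy=overall_accuracy(cm),
    )


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc_curves(
    true_labels, probabilities: np.ndarray,
    class_order: tuple[str, ...] | list[str],
) -> dict[str, dict]:
    """One-vs-rest ROC per class by threshold sweep, area by trapezoids.

    Classes absent from the truth are skipped with a warning.  Returns
    ``{class: {"fpr": ..., "tpr": ..., "auc": ...}}``.
    """
    from sklearn.metrics import auc, roc_curve

    true_labels = np.asarray(true_labels)
    probabilities = np.asarray(probabilities, dtype=float)
    out: dict[str, dict] = {}
    for j, name in enumerate(class_order):
        truth = (true_labels == name).astype(int)
        if truth.sum() == 0:
            warnings.warn(f"roc_curves: class {name!r} absent from truth; "
                          "skipping", stacklevel=2)
            continue
        if truth.sum() == truth.size:
            warnings.warn(f"roc_curves: class {name!r} has no negatives; "
                          "skipping", stacklevel=2)
            continue
        fpr, tpr, _ = roc_curve(truth, probabilities[:, j])
        out[name] = {"fpr": fpr, "tpr": tpr, "auc": float(auc(fpr, tpr))}
    return out


# ---------------------------------------------------------------------------
# reference matrix
# ---------------------------------------------------------------------------

def load_reference_confusion(path: str | Path | None = None) -> ConfusionMatrix:
    """Load the shipped published reference confusion matrix (or any CSV
    with class names as the index/header, rows actual)."""
    if path is None:
        ref = resources.files("btc").joinpath("data/reference_confusion.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, index_col=0)
    else:
        df = pd.read_csv(path, index_col=0)
    return ConfusionMatrix(df.values, tuple(df.index))
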