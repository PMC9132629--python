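"""Confusion matrix and one-vs-rest classification metrics.

Multiclass sensitivity, specificity, precision, and F-measure are computed
one-vs-rest per class by collapsing the K×K confusion matrix to a 2×2 table
for that class; macro averages are unweighted means over classes. Ratios of
the form 0/0 are reported as 0 and flagged so degenerate classes are visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bpnn import BPNNModel, predict
from .vectorize import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "EvalReport",
    "confusion",
    "metrics_from_confusion",
    "evaluate_pipeline",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K×K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_names: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        K = len(self.class_names)
        if counts.shape != (K, K):
            raise ValueError("counts must be K x K")
        if counts.size and counts.min() < 0:
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_text(self) -> str:
        names = self.class_names
        width = max(len(n) for n in names) if names else 4
        width = max(width, max((len(str(v)) for v in self.counts.ravel()), default=1))
        header = " " * (width + 2) + "  ".join(f"{n:>{width}}" for n in names)
        rows = [
            f"{names[i]:>{width}}  " + "  ".join(f"{v:>{width}}" for v in self.counts[i])
            for i in range(len(names))
        ]
        return "\n".join([header, *rows])


@dataclass(frozen=True)
class ClassMetrics:
    name: str
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    undefined: tuple[str, ...] = ()  # metrics that were 0/0, reported as 0


@dataclass(frozen=True)
class EvalReport:
    """Per-class and macro-averaged one-vs-rest metrics."""

    per_class: tuple[ClassMetrics, ...]
    overall_accuracy: float
    macro_sensitivity: float
    macro_specificity: float
    macro_f_measure: float

    def as_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_f_measure": self.macro_f_measure,
            "per_class": [
                {
                    "class": m.name,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "precision": m.precision,
                    "f_measure": m.f_measure,
                    "undefined": list(m.undefined),
                }
                for m in self.per_class
            ],
        }

    def as_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True, indent=2)

    def as_text(self) -> str:
        lines = [
            f"overall accuracy   {self.overall_accuracy:.4f}",
            f"macro sensitivity  {self.macro_sensitivity:.4f}",
            f"macro specificity  {self.macro_specificity:.4f}",
            f"macro F-measure    {self.macro_f_measure:.4f}",
            "",
            f"{'class':<12} {'sens':>8} {'spec':>8} {'prec':>8} {'F':>8}",
        ]
        for m in self.per_class:
            flag = " *" if m.undefined else ""
            lines.append(
                f"{m.name:<12} {m.sensitivity:>8.4f} {m.specificity:>8.4f} "
                f"{m.precision:>8.4f} {m.f_measure:>8.4f}{flag}"
            )
        if any(m.undefined for m in self.per_class):
            lines.append("* some ratios were 0/0 and reported as 0")
        return "\n".join(lines)


def confusion(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    class_names: Sequence[str],
) -> ConfusionMatrix:
    """Counts(i, j) = number of documents with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    K = len(class_names)
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= K or y_pred.min() < 0 or y_pred.max() >= K
    ):
        raise ValueError(f"class codes must lie in 0..{K - 1}")
    counts = np.zeros((K, K), dtype=np.int64)
    np.add.at(counts, (y_true, y_pred), 1)
    return ConfusionMatrix(counts=counts, class_names=tuple(class_names))


def _safe_ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> EvalReport:
    """One-vs-rest metrics per class plus unweighted macro averages.

    Per class c: TP = cm(c,c), FN = row c − TP, FP = column c − TP,
    TN = total − TP − FN − FP; sensitivity = TP/(TP+FN), specificity =
    TN/(TN+FP), precision = TP/(TP+FP), F = harmonic mean of precision and
    sensitivity. Overall accuracy is trace/total.
    """
    total = cm.total
    if total == 0:
        raise ValueError("cannot compute metrics of an empty confusion matrix")
    per_class: list[ClassMetrics] = []
    counts = cm.counts.astype(np.float64)
    for c, name in enumerate(cm.class_names):
        tp = counts[c, c]
        fn = counts[c].sum() - tp
        fp = counts[:, c].sum() - tp
        tn = total - tp - fn - fp
        flags: list[str] = []
        sens = _safe_ratio(tp, tp + fn, "sensitivity", flags)
        spec = _safe_ratio(tn, tn + fp, "specificity", flags)
        prec = _safe_ratio(tp, tp + fp, "precision", flags)
        f = _safe_ratio(2 * prec * sens, prec + sens, "f_measure", flags)
        per_class.append(
            ClassMetrics(
                name=name,
                sensitivity=sens,
                specificity=spec,
                precision=prec,
                f_measure=f,
                undefined=tuple(flags),
            )
        )
    return EvalReport(
        per_class=tuple(per_class),
        overall_accuracy=float(np.trace(cm.counts)) / total,
        macro_sensitivity=float(np.mean([m.sensitivity for m in per_class])),
        macro_specificity=float(np.mean([m.specificity for m in per_class])),
        macro_f_measure=float(np.mean([m.f_measure for m in per_class])),
    )


def evaluate_pipeline(model: BPNNModel, test: FeatureMatrix) -> EvalReport:
    """Predict the test matrix with the network and score the predictions."""
    y_pred = predict(model, test)
    cm = confusion(test.labels, y_pred, test.class_names)
    return metrics_from_confusion(cm)
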