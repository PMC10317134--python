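"""Confusion matrices, per-class and weighted classification metrics, and
scan-grid difference maps.

Rows of the confusion matrix are actual classes, columns predicted classes,
in the fixed order carbon, amorphous_ice, crystalline_ice, mixed.  Per-class
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); overall
accuracy = trace/total.  Weighted averages weight each class by its actual
support, which makes weighted recall algebraically identical to accuracy.
Zero-denominator metrics are reported as NaN (undefined) and enter the
weighted averages with weight 0 via their (zero) support.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .labeling import CLASS_NAMES

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "metrics", "difference_map"]


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (n_classes, n_classes), rows actual, cols predicted
    class_names: tuple[str, ...] = CLASS_NAMES

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp()

    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp()

    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def confusion(
    actual: np.ndarray,
    predicted: np.ndarray,
    n_classes: int = 4,
    mask: np.ndarray | None = None,
) -> ConfusionMatrix:
    """Count actual-vs-predicted classes over a scan grid (or any arrays of
    matching shape); ``mask`` optionally restricts to a subset of points."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {actual.shape} vs {predicted.shape}")
    a = actual.ravel()
    p = predicted.ravel()
    if mask is not None:
        m = np.asarray(mask, bool).ravel()
        a, p = a[m], p[m]
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (a.astype(int), p.astype(int)), 1)
    names = CLASS_NAMES if n_classes == len(CLASS_NAMES) else tuple(f"class{i}" for i in range(n_classes))
    return ConfusionMatrix(counts=cm, class_names=names)


@dataclass
class MetricsReport:
    """Per-class and support-weighted classification metrics.

    Per-class arrays hold NaN where the metric is 0/0-undefined (no
    predictions or no instances of that class)."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    class_names: tuple[str, ...] = CLASS_NAMES
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def clean(x):
            return [None if np.isnan(v) else float(v) for v in x]

        return {
            "class_names": list(self.class_names),
            "precision": clean(self.precision),
            "recall": clean(self.recall),
            "f1": clean(self.f1),
            "support": [int(s) for s in self.support],
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def to_text(self) -> str:
        w = max(len(n) for n in self.class_names)
        lines = [f"{'class':<{w}}  precision  recall  f1      support"]
        for i, name in enumerate(self.class_names):
            def fmt(v):
                return "   NA " if np.isnan(v) else f"{v:6.3f}"
            lines.append(
                f"{name:<{w}}  {fmt(self.precision[i])}     {fmt(self.recall[i])}  {fmt(self.f1[i])}  {int(self.support[i]):7d}"
            )
        lines.append(
            f"accuracy {self.accuracy:.4f} | weighted precision {self.weighted_precision:.4f} "
            f"recall {self.weighted_recall:.4f} f1 {self.weighted_f1:.4f}"
        )
        return "\n".join(lines)


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Derive the metric report from a confusion matrix.

    Undefined (0/0) per-class values are NaN; weighting uses actual-class
    supports, so zero-support classes drop out of the averages, and NaN
    metrics of supported classes count as 0 there.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn = cm.tp().astype(float), cm.fp().astype(float), cm.fn().astype(float)
    support = cm.support().astype(float)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    p0, r0 = np.nan_to_num(precision), np.nan_to_num(recall)
    denom = p0 + r0
    f1 = np.where(denom > 0, 2 * p0 * r0 / np.where(denom > 0, denom, 1.0), np.nan)
    accuracy = float(tp.sum() / total)
    wsum = support.sum()

    def wavg(v):
        return float(np.nansum(np.nan_to_num(v) * support) / wsum)

    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        support=cm.support(),
        accuracy=accuracy,
        weighted_precision=wavg(precision),
        weighted_recall=wavg(recall),
        weighted_f1=wavg(f1),
        class_names=cm.class_names,
    )


def difference_map(actual: np.ndarray, predicted: np.ndarray):
    """Boolean grid of misclassified scan points plus per-actual-class error
    counts (the red points of a prediction-difference figure)."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if actual.shape != predicted.shape:
        raise ValueError(f"shape mismatch: {actual.shape} vs {predicted.shape}")
    diff = actual != predicted
    per_class = {
        CLASS_NAMES[c]: int(np.sum(diff & (actual == c)))
        for c in np.unique(actual).astype(int)
    }
    return diff, per_class
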