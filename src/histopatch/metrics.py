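"""Evaluation metrics: confusion matrix and one-vs-rest per-class scores.

Per-class metrics come from the one-vs-rest TP/FP/FN/TN reading of the
confusion matrix: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the
harmonic mean of the two, and per-class accuracy the four-term
(TP+TN)/total — which is why per-class accuracy differs from recall.
Overall accuracy is trace/total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from histopatch.io_dataset import CLASSES


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    for arr, which in ((y_true, "true"), (y_pred, "predicted")):
        bad = (arr < 0) | (arr >= n_classes)
        if bad.any():
            raise ValueError(f"{which} labels outside [0, {n_classes}): {np.unique(arr[bad])}")
    return _sk_confusion(y_true, y_pred, labels=np.arange(n_classes))


def precision_recall_f1_accuracy(confusion: np.ndarray, class_index: int) -> tuple[float, float, float, float]:
    """One-vs-rest (precision, recall, f1, accuracy) for one class.

    0/0 ratios resolve to 0 with a warning.
    """
    confusion = np.asarray(confusion)
    total = confusion.sum()
    tp = confusion[class_index, class_index]
    fp = confusion[:, class_index].sum() - tp
    fn = confusion[class_index, :].sum() - tp
    tn = total - tp - fp - fn

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (0/0) for class {class_index}; reporting 0")
            return 0.0
        return float(num / den)

    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1")
    accuracy = ratio(tp + tn, total, "accuracy")
    return precision, recall, f1, accuracy


@dataclass
class MetricsReport:
    confusion: np.ndarray
    per_class: dict[str, dict[str, float]]
    overall_accuracy: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "per_class": self.per_class,
            "overall_accuracy": self.overall_accuracy,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate(y_true, y_pred, class_names: tuple[str, ...] = CLASSES) -> MetricsReport:
    """Full report: confusion matrix, per-class one-vs-rest metrics, and
    overall accuracy (trace/total)."""
    cm = confusion_matrix(y_true, y_pred, len(class_names))
    per_class = {}
    for i, name in enumerate(class_names):
        p, r, f1, acc = precision_recall_f1_accuracy(cm, i)
        per_class[name] = {"precision": p, "recall": r, "f1": f1, "accuracy": acc}
    return MetricsReport(
        confusion=cm,
        per_class=per_class,
        overall_accuracy=float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0,
    )
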