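"""Classification metrics: confusion matrix, accuracy, per-class precision/recall/F1.

The confusion matrix is 3x3 with rows = true stage, columns = predicted stage
(order normal, acute, chronic). Accuracy is trace/total; per class,
precision = column-correct / column-sum, recall = row-correct / row-sum,
F1 = 2PR / (P + R). Zero denominators yield 0 with a warning so reports stay
total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import Stage

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "accuracy",
    "precision_recall_f1",
    "evaluate",
]

N_CLASSES = 3
CLASS_NAMES = [Stage.NORMAL.value, Stage.ACUTE.value, Stage.CHRONIC.value]


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """Entry (i, j) = number of samples with true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D and equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= N_CLASSES):
            raise ValueError(f"{name} labels must lie in 0..{N_CLASSES - 1}")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(confusion: np.ndarray) -> float:
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def precision_recall_f1(
    confusion: np.ndarray, class_idx: int
) -> tuple[float, float, float]:
    confusion = np.asarray(confusion)
    col = confusion[:, class_idx].sum()
    row = confusion[class_idx, :].sum()
    tp = confusion[class_idx, class_idx]

    def safe(num, den, what):
        if den == 0:
            warnings.warn(
                f"{what} undefined for class {class_idx} (zero denominator); "
                "reporting 0",
                RuntimeWarning,
                stacklevel=3,
            )
            return 0.0
        return float(num / den)

    precision = safe(tp, col, "precision")
    recall = safe(tp, row, "recall")
    f1 = safe(2 * precision * recall, precision + recall, "F1")
    return precision, recall, f1


@dataclass
class EvalReport:
    """Complete evaluation of a three-class prediction."""

    confusion: np.ndarray
    accuracy: float
    precision: tuple[float, float, float]
    recall: tuple[float, float, float]
    f1: tuple[float, float, float]
    n_samples: int

    def to_dict(self) -> dict:
        row_sums = self.confusion.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            rates = np.where(row_sums > 0, self.confusion / row_sums, 0.0)
        return {
            "n_samples": self.n_samples,
            "accuracy": self.accuracy,
            "class_names": CLASS_NAMES,
            "confusion_counts": self.confusion.tolist(),
            "confusion_row_rates": rates.tolist(),
            "precision": list(self.precision),
            "recall": list(self.recall),
            "f1": list(self.f1),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_to_csv(self, path) -> None:
        pd.DataFrame(
            self.confusion,
            index=[f"true_{c}" for c in CLASS_NAMES],
            columns=[f"pred_{c}" for c in CLASS_NAMES],
        ).to_csv(path)


def evaluate(y_true, y_pred) -> EvalReport:
    """Confusion matrix, accuracy, and per-class precision/recall/F1."""
    cm = confusion_matrix(y_true, y_pred)
    prf = [precision_recall_f1(cm, k) for k in range(N_CLASSES)]
    return EvalReport(
        confusion=cm,
        accuracy=accuracy(cm),
        precision=tuple(p for p, _, _ in prf),
        recall=tuple(r for _, r, _ in prf),
        f1=tuple(f for _, _, f in prf),
        n_samples=int(cm.sum()),
    )
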