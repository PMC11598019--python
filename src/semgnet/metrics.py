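"""Classification metrics and subject-level aggregation.

Macro-averaged F1 is used throughout: the gesture classes are mildly
imbalanced (gesture runs differ in length after windowing), and micro-F1
would just duplicate accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

__all__ = ["MetricsReport", "compute_metrics", "mean_std_table"]


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    confusion: np.ndarray
    n_samples: int
    best_epoch: int | None = None

    def summary(self) -> str:
        return f"accuracy={self.accuracy:.4f} macro-F1={self.f1:.4f} (n={self.n_samples})"


def compute_metrics(predictions, truths, n_classes: int,
                    best_epoch: int | None = None) -> MetricsReport:
    """Accuracy, macro-F1 and the K×K confusion matrix.

    Classes absent from ``truths`` are excluded from the macro-F1 average
    (with a warning); the confusion matrix keeps all K rows/columns.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape or predictions.size == 0:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    labels = np.arange(n_classes)
    if (predictions.min() < 0 or predictions.max() >= n_classes
            or truths.min() < 0 or truths.max() >= n_classes):
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    present = np.unique(truths)
    if len(present) < n_classes:
        warnings.warn(f"classes {sorted(set(labels) - set(present))} absent "
                      "from truths; excluded from macro-F1")
    f1 = f1_score(truths, predictions, labels=present, average="macro",
                  zero_division=0)
    return MetricsReport(
        accuracy=float(accuracy_score(truths, predictions)),
        f1=float(f1),
        confusion=confusion_matrix(truths, predictions, labels=labels),
        n_samples=int(truths.size),
        best_epoch=best_epoch,
    )


def mean_std_table(rows: dict[str, dict[str, float]],
                   columns=("accuracy", "f1")) -> str:
    """Per-subject rows with a 'mean ± std' footer, two decimals."""
    lines = ["subject\t" + "\t".join(columns)]
    for sid, vals in rows.items():
        lines.append(sid + "\t" + "\t".join(f"{vals[c]:.2f}" for c in columns))
    if rows:
        arr = {c: np.array([v[c] for v in rows.values()]) for c in columns}
        lines.append("mean±std\t" + "\t".join(
            f"{arr[c].mean():.2f} ± {arr[c].std():.2f}" for c in columns))
    return "\n".join(lines)
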