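"""Confusion counting and per-class accuracy percentages.

The confusion summary follows the three-row layout common in clinical
classification reports: per-category correctly-classified counts, actual
counts, and the accuracy percentage of each category plus the total.
Percentages are computed exactly (rational arithmetic) and rounded
half-even to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path

import numpy as np

from .exceptions import InputError

__all__ = ["ConfusionTable", "confusion", "accuracy_percent"]


def accuracy_percent(correct: int, total: int) -> float:
    """100 * correct / total, rounded half-even to two decimals.

    Computed in exact decimal arithmetic so printed-table values are
    reproduced without floating-point rounding surprises.
    """
    if total < 1:
        raise InputError("total must be >= 1")
    if not 0 <= correct <= total:
        raise InputError(f"need 0 <= correct <= total, got {correct}/{total}")
    value = (Decimal(100) * Decimal(correct) / Decimal(total)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_EVEN
    )
    return float(value)


@dataclass
class ConfusionTable:
    """Per-category (correct, actual) counts with totals."""

    class_values: np.ndarray   # category identifiers, in report order
    correct: np.ndarray        # correctly classified per category
    actual: np.ndarray         # ground-truth count per category

    def __post_init__(self) -> None:
        self.class_values = np.asarray(self.class_values)
        self.correct = np.asarray(self.correct, dtype=int)
        self.actual = np.asarray(self.actual, dtype=int)
        if not (self.correct <= self.actual).all() or (self.correct < 0).any():
            raise InputError("need 0 <= correct <= actual in every category")

    @property
    def total_correct(self) -> int:
        return int(self.correct.sum())

    @property
    def total_actual(self) -> int:
        return int(self.actual.sum())

    def accuracy(self, category=None) -> float:
        """Accuracy percentage for one category, or overall when omitted."""
        if category is None:
            return accuracy_percent(self.total_correct, self.total_actual)
        idx = int(np.nonzero(self.class_values == category)[0][0])
        return accuracy_percent(int(self.correct[idx]), int(self.actual[idx]))

    def to_frame(self):
        import pandas as pd

        cols = [str(v) for v in self.class_values] + ["Total"]
        rows = {
            "Classification results": [*self.correct, self.total_correct],
            "Actual results": [*self.actual, self.total_actual],
            "Accuracy (%)": [
                accuracy_percent(int(c), int(a))
                for c, a in zip(self.correct, self.actual)
            ]
            + [self.accuracy()],
        }
        return pd.DataFrame(rows, index=cols).T

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def confusion(pred_labels, true_labels, mask=None) -> ConfusionTable:
    """Per-class correct/actual counts between two label images.

    ``mask`` restricts counting: either a boolean array of the image shape
    or a sequence of (row, col) coordinates.  Default is all pixels.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise InputError(f"shape mismatch: {pred.shape} vs {true.shape}")
    if mask is not None:
        mask = np.asarray(mask)
        if mask.dtype == bool:
            if mask.shape != true.shape:
                raise InputError("boolean mask shape must match labels")
            pred, true = pred[mask], true[mask]
        else:
            coords = mask.reshape(-1, 2).astype(int)
            pred = pred[coords[:, 0], coords[:, 1]]
            true = true[coords[:, 0], coords[:, 1]]
    class_values = np.unique(true)
    correct = np.asarray(
        [int(np.sum((true == v) & (pred == v))) for v in class_values]
    )
    actual = np.asarray([int(np.sum(true == v)) for v in class_values])
    return ConfusionTable(class_values=class_values, correct=correct, actual=actual)
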