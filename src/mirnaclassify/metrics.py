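"""Confusion-matrix metrics for imbalanced two-class evaluation.

Under severe class imbalance overall accuracy collapses onto the majority
class's specificity (Acc ~ SP when negatives dominate), so the headline
statistic here is the geometric mean G_m = sqrt(SE x SP), which is high
only when both classes are classified well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence, Tuple

import numpy as np

from .errors import LabelError, UndefinedMetricError


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN = correctly classified positives/negatives; FN/FP = the
    misclassified positives/negatives (standard convention)."""

    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def n_pos(self) -> int:
        return self.TP + self.FN

    @property
    def n_neg(self) -> int:
        return self.TN + self.FP


def _as_binary(a: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 1:
        raise LabelError(f"{name} must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise LabelError(f"{name} must contain only 0/1 labels")
    return arr.astype(int)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN; label 1 marks a real pre-miRNA."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise LabelError(
            f"length mismatch: {yt.shape[0]} true vs {yp.shape[0]} predicted"
        )
    return ConfusionCounts(
        TP=int(((yt == 1) & (yp == 1)).sum()),
        TN=int(((yt == 0) & (yp == 0)).sum()),
        FP=int(((yt == 0) & (yp == 1)).sum()),
        FN=int(((yt == 1) & (yp == 0)).sum()),
    )


def se_sp(counts: ConfusionCounts) -> Tuple[float, float]:
    """SE = TP/(TP+FN), SP = TN/(TN+FP)."""
    if counts.n_pos == 0 or counts.n_neg == 0:
        raise UndefinedMetricError(
            f"need both classes present (n_pos={counts.n_pos}, n_neg={counts.n_neg})"
        )
    return counts.TP / counts.n_pos, counts.TN / counts.n_neg


def g_mean(se: float, sp: float) -> float:
    """Geometric mean sqrt(SE x SP); accepts either fractions in [0, 1]
    or percentages in [0, 100] (both inputs must be on the same scale)."""
    hi = 100.0 if (se > 1.0 or sp > 1.0) else 1.0
    if not (0.0 <= se <= hi and 0.0 <= sp <= hi):
        raise UndefinedMetricError(f"SE={se}, SP={sp} outside [0, {hi}]")
    return math.sqrt(se * sp)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP+TN)/(TP+TN+FP+FN); reported but never used for model selection."""
    total = counts.TP + counts.TN + counts.FP + counts.FN
    if total == 0:
        raise UndefinedMetricError("empty confusion counts")
    return (counts.TP + counts.TN) / total


def as_percent(x: float, decimals: int = 2) -> float:
    """Fraction -> percentage rounded half-up, matching table formatting."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


def round_half_up(x: float, decimals: int = 2) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def evaluate(y_true: Sequence[int], y_pred: Sequence[int]) -> dict:
    """Full metric panel as a flat dict (percentages rounded to 2 dp)."""
    c = confusion(y_true, y_pred)
    se, sp = se_sp(c)
    return {
        "TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN,
        "SE": as_percent(se), "SP": as_percent(sp),
        "Acc": as_percent(accuracy(c)), "Gm": as_percent(g_mean(se, sp)),
    }
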