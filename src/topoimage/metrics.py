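"""Confusion-matrix metrics for binary segmentation masks.

Pixels inside the predicted segmentation are positives.  The four metrics are
accuracy, the Sorensen-Dice coefficient ``2TP / (2TP + FP + FN)``, the
Matthews correlation coefficient, and the inclusion score (recall)
``TP / (TP + FN)``.

MCC is computed with the square root of the product denominator,
``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))`` — the standard
definition, which is what makes the stated range [-1, 1] hold.  An unrooted
variant is available behind a flag for comparison.  Metrics with a zero
denominator return 0.0 and are reported as degenerate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "confusion",
    "accuracy",
    "dice",
    "mcc",
    "inclusion",
    "evaluate",
    "batch_evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts of a predicted vs. a ground-truth mask."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        return 0.0
    return (c.tp + c.tn) / c.total


def dice(c: ConfusionCounts) -> float:
    """2TP / (2TP + FP + FN); 0.0 (degenerate) when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 0.0
    return 2 * c.tp / denom


def inclusion(c: ConfusionCounts) -> float:
    """Recall TP / (TP + FN); 0.0 (degenerate) when the truth mask is empty."""
    denom = c.tp + c.fn
    if denom == 0:
        return 0.0
    return c.tp / denom


def mcc(c: ConfusionCounts, rooted: bool = True) -> float:
    """Matthews correlation coefficient.

    ``rooted=True`` (default) uses the standard square-root denominator so the
    value lies in [-1, 1]; ``rooted=False`` divides by the raw product.
    Degenerate denominators return 0.0.
    """
    num = c.tp * c.tn - c.fp * c.fn
    prod = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if prod == 0:
        return 0.0
    return num / (math.sqrt(prod) if rooted else prod)


def is_degenerate(c: ConfusionCounts) -> dict[str, bool]:
    """Which metrics are undefined (returned as flagged 0.0) for these counts."""
    return {
        "dice": 2 * c.tp + c.fp + c.fn == 0,
        "inclusion": c.tp + c.fn == 0,
        "mcc": (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn) == 0,
    }


def evaluate(pred: np.ndarray, truth: np.ndarray) -> dict[str, float]:
    """All four metrics of one predicted/truth mask pair."""
    c = confusion(pred, truth)
    return {
        "accuracy": accuracy(c),
        "dice": dice(c),
        "mcc": mcc(c),
        "inclusion": inclusion(c),
    }


def batch_evaluate(pairs, group: str = "") -> pd.DataFrame:
    """Per-image metrics plus a mean row for a list of (pred, truth) pairs.

    Returns a DataFrame with one row per pair and a final ``mean`` row, the
    shape used to average segmenter performance across a corpus.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no mask pairs to evaluate")
    rows = []
    for i, (pred, truth) in enumerate(pairs):
        row = {"group": group, "image": i}
        row.update(evaluate(pred, truth))
        rows.append(row)
    df = pd.DataFrame(rows)
    mean = df[["accuracy", "dice", "mcc", "inclusion"]].mean()
    mean_row = {"group": group, "image": "mean", **mean.to_dict()}
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
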