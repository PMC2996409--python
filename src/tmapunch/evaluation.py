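"""Confusion-matrix scoring and dataset-splitting harness.

Affected tiles are the positive class.  Tiles labelled non-informative by
either the prediction or the truth are excluded from scoring, as is any
tile with a missing (discordant) truth label.  Percentages are reported as
floor-truncated integers -- e.g. a raw accuracy of 83.9% prints as 83 --
which is the convention all reported reference percentages follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .errors import UndefinedMetricError
from .tiling import AFFECTED, NON_INFORMATIVE, UNAFFECTED

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "percent_metrics",
    "split_dataset",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts over affected-vs-unaffected tiles."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_matrix(
    predicted: Sequence[Optional[str]], truth: Sequence[Optional[str]]
) -> ConfusionMatrix:
    """Score predictions against truth labels.

    ``non_informative`` (or missing) labels on either side exclude the tile.
    """
    if len(predicted) != len(truth):
        raise ValueError(
            f"length mismatch: {len(predicted)} predictions, {len(truth)} truths"
        )
    tp = fp = fn = tn = 0
    for p, t in zip(predicted, truth):
        if p in (None, NON_INFORMATIVE) or t in (None, NON_INFORMATIVE):
            continue
        if p not in (AFFECTED, UNAFFECTED) or t not in (AFFECTED, UNAFFECTED):
            raise ValueError(f"unknown label pair ({p!r}, {t!r})")
        if p == AFFECTED and t == AFFECTED:
            tp += 1
        elif p == AFFECTED:
            fp += 1
        elif t == AFFECTED:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def percent_metrics(cm: ConfusionMatrix) -> Tuple[int, int, int]:
    """(accuracy, sensitivity, specificity) as floor-truncated percentages."""
    if cm.total == 0:
        raise UndefinedMetricError("empty confusion matrix")
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no positive tiles: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no negative tiles: specificity undefined")
    accuracy = math.floor(100 * (cm.tp + cm.tn) / cm.total)
    sensitivity = math.floor(100 * cm.tp / (cm.tp + cm.fn))
    specificity = math.floor(100 * cm.tn / (cm.tn + cm.fp))
    return accuracy, sensitivity, specificity


def split_dataset(
    n: int, sizes: Tuple[int, int, int], seed: int = 0
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint (train, tune, validation) index sets covering range(n).

    Sizes must sum to ``n``.  Deterministic per seed; re-seeding supports
    repeated cross-validation rounds.
    """
    if len(sizes) != 3 or any(s < 0 for s in sizes):
        raise ValueError("sizes must be three non-negative counts")
    if sum(sizes) != n:
        raise ValueError(f"sizes {sizes} do not sum to n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    a, b, _ = sizes
    return perm[:a], perm[a : a + b], perm[a + b :]
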