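"""Pixel-level agreement metrics between binary masks.

All five metrics (IoU, F1/Dice, accuracy, sensitivity, specificity) derive
from a single confusion-count computation. Conventions for degenerate
denominators:

* both masks empty ("no finding" vs "no finding") -> every metric is 1.0,
  i.e. unanimous empties are perfect agreement;
* any other zero denominator resolves to 1.0 (the condition is vacuously
  satisfied), except IoU/F1 between an empty and a non-empty mask, which
  are 0 by their formulas.

Cohort summaries are macro-averaged: metrics are computed per frame and
then averaged, with the sample standard deviation (n-1 denominator; a
single report yields sd = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError
from .masks import BinaryMask


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise confusion counts of a prediction against a reference."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """All five agreement metrics from one confusion computation."""

    iou: float
    f1: float
    accuracy: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts

    def value(self, metric: str) -> float:
        if metric not in ("iou", "f1", "accuracy", "sensitivity", "specificity"):
            raise DomainError(f"unknown metric {metric!r}")
        return getattr(self, metric)


@dataclass(frozen=True)
class CohortSummary:
    """Mean +/- sd of one metric over a cohort of reports."""

    metric: str
    mean: float
    sd: float
    n: int


def confusion(pred: BinaryMask, ref: BinaryMask) -> ConfusionCounts:
    """Confusion counts of *pred* against *ref* (same dimensions required)."""
    pred.require_comparable(ref)
    p, r = pred.data, ref.data
    tp = int(np.count_nonzero(p & r))
    fp = int(np.count_nonzero(p & ~r))
    fn = int(np.count_nonzero(~p & r))
    tn = pred.n_pixels - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: int, den: int) -> float:
    # zero denominator -> vacuous perfection
    return 1.0 if den == 0 else num / den


def iou(pred: BinaryMask, ref: BinaryMask) -> float:
    """Intersection over union; both-empty pairs agree perfectly (1.0)."""
    c = confusion(pred, ref)
    return _ratio(c.tp, c.tp + c.fp + c.fn)


def f1(pred: BinaryMask, ref: BinaryMask) -> float:
    """Dice / F1 score; both-empty pairs agree perfectly (1.0)."""
    c = confusion(pred, ref)
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn)


def evaluate(pred: BinaryMask, ref: BinaryMask) -> MetricReport:
    """Compute all five metrics from a single confusion computation."""
    c = confusion(pred, ref)
    return MetricReport(
        iou=_ratio(c.tp, c.tp + c.fp + c.fn),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        counts=c,
    )


def summarize(reports: Sequence[MetricReport], metric: str) -> CohortSummary:
    """Mean +/- sample sd of one named metric over *reports*."""
    if not reports:
        raise DomainError("cannot summarize an empty collection of reports")
    values = [r.value(metric) for r in reports]
    n = len(values)
    mean = float(np.mean(values))
    sd = 0.0 if n == 1 else float(np.std(values, ddof=1))
    return CohortSummary(metric=metric, mean=mean, sd=sd, n=n)


def dice_from_iou(j: float) -> float:
    """Closed-form Dice-Jaccard relation: f1 = 2*iou / (1 + iou)."""
    if not 0.0 <= j <= 1.0 or math.isnan(j):
        raise DomainError(f"iou outside [0, 1]: {j}")
    return 2.0 * j / (1.0 + j)
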