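"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-pixel Python loops, no shared
code with the package) so it can serve as a second, independent route to
the same quantities.
"""

from __future__ import annotations

import numpy as np


def pixel_loop_metrics(pred: np.ndarray, ref: np.ndarray) -> dict[str, float]:
    """All five agreement metrics by per-pixel enumeration."""
    assert pred.shape == ref.shape
    tp = fp = fn = tn = 0
    for r in range(pred.shape[0]):
        for c in range(pred.shape[1]):
            p, g = bool(pred[r, c]), bool(ref[r, c])
            if p and g:
                tp += 1
            elif p and not g:
                fp += 1
            elif not p and g:
                fn += 1
            else:
                tn += 1
    total = tp + fp + fn + tn

    def ratio(num: int, den: int) -> float:
        return 1.0 if den == 0 else num / den

    return {
        "iou": ratio(tp, tp + fp + fn),
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
        "accuracy": ratio(tp + tn, total),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
    }


def pixel_loop_votes(masks: list[np.ndarray]) -> np.ndarray:
    """Per-pixel vote tally by explicit looping."""
    h, w = masks[0].shape
    counts = np.zeros((h, w), dtype=int)
    for r in range(h):
        for c in range(w):
            counts[r, c] = sum(bool(m[r, c]) for m in masks)
    return counts


def _disc_offsets(r: int) -> list[tuple[int, int]]:
    return [
        (dr, dc)
        for dr in range(-r, r + 1)
        for dc in range(-r, r + 1)
        if dr * dr + dc * dc <= r * r
    ]


def naive_dilate(arr: np.ndarray, r: int) -> np.ndarray:
    h, w = arr.shape
    out = np.zeros_like(arr)
    offs = _disc_offsets(r)
    for rr, cc in zip(*np.nonzero(arr)):
        for dr, dc in offs:
            r2, c2 = rr + dr, cc + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                out[r2, c2] = True
    return out


def naive_erode(arr: np.ndarray, r: int) -> np.ndarray:
    h, w = arr.shape
    out = np.zeros_like(arr)
    offs = _disc_offsets(r)
    for rr, cc in zip(*np.nonzero(arr)):
        keep = True
        for dr, dc in offs:
            r2, c2 = rr + dr, cc + dc
            if not (0 <= r2 < h and 0 <= c2 < w) or not arr[r2, c2]:
                keep = False
                break
        out[rr, cc] = keep
    return out


def oracle_jitter_annotation(
    gt: np.ndarray, jitter: int, noise: float, rng: np.random.Generator
) -> np.ndarray:
    """Honest-annotator noise model re-implemented with naive morphology.

    Mirrors the implementation's draw protocol (miss draw, signed radius,
    boundary-band flips) so both consume identical random streams.
    """
    rng.random()  # the miss draw (miss probability 0 here)
    arr = gt.copy()
    radius = int(rng.integers(-jitter, jitter + 1))
    if radius > 0:
        arr = naive_dilate(arr, radius)
    elif radius < 0:
        arr = naive_erode(arr, -radius)
    band = naive_dilate(arr, 1) & ~naive_erode(arr, 1)
    flips = band & (rng.random(arr.shape) < noise)
    return arr ^ flips


#: Mean IoU of the jitter=2 / noise=0.05 annotator against a 64x64
#: radius-12 disc, over seeds 0..499 of the naive oracle above:
#: mean 0.8375, sd 0.0949, sem 0.0042. Band = mean +/- 3 sem.
JITTER2_NOISE05_IOU_BAND = (0.8248, 0.8502)
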