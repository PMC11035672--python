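"""Pixel-wise majority-vote fusion of multiple annotations of one task.

The vote threshold ``mv`` is an absolute per-pixel count: a pixel enters
the consensus iff at least ``mv`` of the contributing masks contain it.
``mv = 1`` yields the union of the annotations, ``mv = len(annotations)``
the intersection. No ties are possible under a count threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Collection, Sequence

import numpy as np

from .config import CampaignConfig
from .errors import ComparabilityError, ConfigurationError, DomainError
from .masks import Annotation, BinaryMask


@dataclass(frozen=True)
class ConsensusRecord:
    """The fused mask for one (frame, structure) task."""

    frame_id: str
    structure: str
    mask: BinaryMask
    contributor_ids: tuple[str, ...]
    vote_threshold_used: int
    n_used: int


def _check_dims(masks: Sequence[BinaryMask]) -> None:
    first = masks[0]
    for m in masks[1:]:
        if m.shape != first.shape:
            raise ComparabilityError(
                f"mask dimensions differ: {first.shape} vs {m.shape}"
            )


def vote_counts(annotations: Sequence[BinaryMask]) -> np.ndarray:
    """Per-pixel tally: how many of the masks contain each pixel."""
    if not annotations:
        raise DomainError("cannot tally votes over an empty collection")
    _check_dims(annotations)
    counts = np.zeros(annotations[0].shape, dtype=np.int64)
    for m in annotations:
        counts += m.data
    return counts


def majority_vote(annotations: Sequence[BinaryMask], mv: int) -> BinaryMask:
    """Fuse masks: foreground = pixels with vote count >= *mv*."""
    if not annotations:
        raise DomainError("cannot build a consensus from zero annotations")
    if not 1 <= mv <= len(annotations):
        raise ConfigurationError(
            f"vote threshold mv={mv} out of range [1, {len(annotations)}]"
        )
    return BinaryMask(vote_counts(annotations) >= mv)


def scaled_vote_threshold(mv: int, n_min: int, n_used: int) -> int:
    """Rescale mv to an actual contributor count, preserving the fraction.

    Identity when ``n_used == n_min``; otherwise ``ceil(mv / n_min * n_used)``
    clamped into ``[1, n_used]``.
    """
    if n_used == n_min:
        return mv
    scaled = math.ceil(mv / n_min * n_used)
    return max(1, min(scaled, n_used))


def build_consensus(
    annotations: Collection[Annotation],
    config: CampaignConfig,
    structure: str,
    qualified: Collection[str] | None = None,
) -> ConsensusRecord | None:
    """Build the consensus record for one task, or ``None`` if pending.

    Only annotations from *qualified* annotators count (``None`` means all
    are qualified, e.g. when gating happened upstream). A task with fewer
    than the configured minimum of qualified annotations is pending, which
    is a normal batch outcome, not an error.
    """
    params = config.structure_params(structure)
    anns = [a for a in annotations if a.structure == structure]
    if len(anns) != len(list(annotations)):
        raise DomainError("annotations mix structures within one task")
    tasks = {a.task for a in anns}
    if len(tasks) > 1:
        raise DomainError(f"annotations span multiple tasks: {sorted(tasks)}")
    if qualified is not None:
        anns = [a for a in anns if a.annotator_id in qualified]
    if len(anns) < params.n_min:
        return None

    n_used = len(anns)
    mv_used = (
        scaled_vote_threshold(params.mv, params.n_min, n_used)
        if params.scale_mv
        else min(params.mv, n_used)
    )
    # deterministic contributor order regardless of input ordering
    anns = sorted(anns, key=lambda a: a.annotator_id)
    fused = majority_vote([a.mask for a in anns], mv_used)
    frame_id = anns[0].frame_id
    return ConsensusRecord(
        frame_id=frame_id,
        structure=structure,
        mask=fused,
        contributor_ids=tuple(a.annotator_id for a in anns),
        vote_threshold_used=mv_used,
        n_used=n_used,
    )
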