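"""Per-task difficulty index and review-threshold QA routing.

The difficulty index (DI) of a task is one minus the mean IoU of each
contributing annotation against the final consensus mask (the annotation's
own vote included — no leave-one-out). DI is 0 when every contributor
matches the consensus exactly (including the unanimous "no finding" case)
and approaches 1 as agreement vanishes.

Tasks whose DI exceeds the review threshold are flagged, and a Bernoulli
draw at the QA sampling rate selects which flagged tasks an expert
actually reviews.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .masks import BinaryMask
from .metrics import iou


@dataclass(frozen=True)
class DifficultyRecord:
    frame_id: str
    structure: str
    di: float
    per_annotator_iou: tuple[float, ...]
    qa_flagged: bool = False
    qa_sampled: bool = False


@dataclass(frozen=True)
class DifficultyProfile:
    """Distribution summary of DI for one structure."""

    structure: str
    median: float
    q1: float
    q3: float
    zero_di_fraction: float
    n: int


def difficulty_index(
    annotations: Sequence[BinaryMask], consensus: BinaryMask
) -> float:
    """DI = 1 - mean IoU of each contributing annotation vs the consensus."""
    if not annotations:
        raise DomainError("difficulty index of an empty contributor set")
    agreements = [iou(m, consensus) for m in annotations]
    return 1.0 - float(np.mean(agreements))


def make_record(
    frame_id: str,
    structure: str,
    annotations: Sequence[BinaryMask],
    consensus: BinaryMask,
) -> DifficultyRecord:
    """Build an unrouted difficulty record for one consensus task."""
    if not annotations:
        raise DomainError("difficulty record needs at least one annotation")
    agreements = tuple(iou(m, consensus) for m in annotations)
    return DifficultyRecord(
        frame_id=frame_id,
        structure=structure,
        di=1.0 - float(np.mean(agreements)),
        per_annotator_iou=agreements,
    )


def flag_for_review(
    record: DifficultyRecord,
    rt: float,
    sampling_rate: float,
    rng: np.random.Generator,
) -> DifficultyRecord:
    """Apply the review-threshold rule: flag iff DI > rt, then sample.

    Only flagged records can be sampled; sampling is a Bernoulli draw at
    *sampling_rate*, reproducible under the generator state.
    """
    if not 0.0 <= rt <= 1.0:
        raise ConfigurationError(f"review threshold out of [0, 1]: {rt}")
    if not 0.0 <= sampling_rate <= 1.0:
        raise ConfigurationError(f"sampling rate out of [0, 1]: {sampling_rate}")
    flagged = record.di > rt
    sampled = bool(flagged and rng.random() < sampling_rate)
    return replace(record, qa_flagged=flagged, qa_sampled=sampled)


def difficulty_profile(
    records: Iterable[DifficultyRecord],
) -> dict[str, DifficultyProfile]:
    """Median / quartiles / zero-DI fraction of DI, per structure.

    Quantiles use midpoint (linear) interpolation. The zero-DI fraction is
    the share of tasks with DI exactly 0, i.e. unanimous tasks, which are
    dominated by "no finding" frames in absence-heavy campaigns.
    """
    by_structure: dict[str, list[float]] = {}
    for rec in records:
        by_structure.setdefault(rec.structure, []).append(rec.di)
    if not by_structure:
        raise DomainError("no difficulty records to profile")
    out = {}
    for structure, dis in by_structure.items():
        arr = np.asarray(dis, dtype=float)
        out[structure] = DifficultyProfile(
            structure=structure,
            median=float(np.median(arr)),
            q1=float(np.quantile(arr, 0.25)),
            q3=float(np.quantile(arr, 0.75)),
            zero_di_fraction=float(np.mean(arr == 0.0)),
            n=len(dis),
        )
    return out
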