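"""Annotator qualification and continuous performance monitoring.

A candidate must first annotate a fixed set of gold training tasks; the
training score (TS) is the mean IoU of those annotations against the
expert references. Once working, gold test tasks are interleaved into the
stream at a configurable cadence; the running score (RS) is the mean IoU
over the most recent window of such tests. An annotator is qualified iff
TS >= ts_min and, whenever an RS exists, RS >= rs_min. Disqualification is
prospective only: it stops future contributions but never rewrites
already-published consensus records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .config import CampaignConfig
from .errors import ConfigurationError, ProtocolError
from .masks import Annotation, ExpertReference, Role
from .metrics import iou


@dataclass(frozen=True)
class AnnotatorProfile:
    """Identity plus training/running scores and qualification state."""

    annotator_id: str
    training_scores: tuple[float, ...] = ()
    running_scores: tuple[float, ...] = ()
    ts: float | None = None
    rs: float | None = None
    qualified: bool = False
    demographics_tag: str | None = None

    @property
    def n_training(self) -> int:
        return len(self.training_scores)

    @property
    def n_running(self) -> int:
        return len(self.running_scores)


def score_training(
    annotator_id: str,
    annotations: Sequence[Annotation],
    references: Mapping[tuple[str, str], ExpertReference],
    config: CampaignConfig,
    demographics_tag: str | None = None,
) -> AnnotatorProfile:
    """Score a candidate on the gold training set and build their profile.

    Exactly ``config.n_training_gold`` training annotations are required,
    each with a registered expert reference. TS is the arithmetic mean of
    the per-task IoUs.
    """
    if len(annotations) != config.n_training_gold:
        raise ProtocolError(
            f"{annotator_id}: expected {config.n_training_gold} training "
            f"gold annotations, got {len(annotations)}"
        )
    scores = []
    for ann in annotations:
        ref = references.get(ann.task)
        if ref is None:
            raise ConfigurationError(
                f"no expert reference registered for training task {ann.task}"
            )
        scores.append(iou(ann.mask, ref.mask))
    ts = float(np.mean(scores))
    profile = AnnotatorProfile(
        annotator_id=annotator_id,
        training_scores=tuple(scores),
        ts=ts,
        demographics_tag=demographics_tag,
    )
    return replace(profile, qualified=is_qualified(profile, config))


def update_running_score(
    profile: AnnotatorProfile,
    annotation: Annotation,
    reference: ExpertReference,
    window: int,
    config: CampaignConfig | None = None,
) -> AnnotatorProfile:
    """Record one running-gold test and refresh RS and qualification.

    RS is the mean IoU over the most recent *window* gold tests. When
    *config* is given, qualification is re-evaluated against it; otherwise
    the qualified flag is left untouched.
    """
    if annotation.role is not Role.RUNNING_GOLD:
        raise ProtocolError(
            f"running score updates require a running_gold annotation, "
            f"got role {annotation.role.value!r}"
        )
    if annotation.task != reference.task:
        raise ConfigurationError(
            f"reference task {reference.task} does not match annotation "
            f"task {annotation.task}"
        )
    scores = profile.running_scores + (iou(annotation.mask, reference.mask),)
    rs = float(np.mean(scores[-window:]))
    updated = replace(profile, running_scores=scores, rs=rs)
    if config is not None:
        updated = replace(updated, qualified=is_qualified(updated, config))
    return updated


def is_qualified(profile: AnnotatorProfile, config: CampaignConfig) -> bool:
    """TS gate and, when an RS exists, the RS gate (conjunction)."""
    if profile.ts is None:
        raise ProtocolError(
            f"{profile.annotator_id} has no training score (never trained)"
        )
    if profile.ts < config.ts_min:
        return False
    return profile.rs is None or profile.rs >= config.rs_min


@dataclass(frozen=True)
class GoldInsertion:
    """A running-gold test inserted into a task stream."""

    reference: ExpertReference


def interleave_gold(
    tasks: Sequence[object],
    gold_pool: Sequence[ExpertReference],
    cadence: int,
    rng: np.random.Generator,
) -> list[object]:
    """Insert running-gold tests into a task stream.

    Before each ordinary task a gold test is inserted with probability
    ``1 / cadence`` (Bernoulli), drawn with replacement from *gold_pool*,
    so on average one gold test per *cadence* ordinary tasks. ``cadence=1``
    alternates gold and ordinary tasks. Deterministic under the generator
    state.
    """
    if cadence < 1:
        raise ConfigurationError(f"cadence must be >= 1, got {cadence}")
    if not gold_pool:
        raise ConfigurationError("gold pool is empty")
    out: list[object] = []
    p = 1.0 / cadence
    for task in tasks:
        if rng.random() < p:
            out.append(GoldInsertion(gold_pool[int(rng.integers(len(gold_pool)))]))
        out.append(task)
    return out
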