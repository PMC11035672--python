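"""End-to-end campaign orchestration and cost/throughput accounting.

A campaign trains every annotator on the gold training set, then routes
each (frame, structure) task to qualified annotators until the configured
minimum number of annotations is reached, interleaving running-gold tests
at the configured cadence. Completed tasks get a majority-vote consensus,
a difficulty record, and review-threshold QA routing; tasks that cannot
gather enough qualified annotations are left pending. The ledger accounts
for every emitted annotation: consensus-contributing ("individual"),
stranded-on-pending, and gold-test annotations are counted separately.

Headline rounding is half-up (so 902.25 h reports as 902 and a 3.4%
share as 3%), with raw values retained alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, NamedTuple, Protocol, Sequence

import numpy as np

from .config import CampaignConfig
from .consensus import ConsensusRecord, build_consensus
from .difficulty import DifficultyRecord, flag_for_review, make_record
from .errors import ConfigurationError, DomainError
from .gating import AnnotatorProfile, score_training, update_running_score
from .masks import Annotation, BinaryMask, ExpertReference, Role, reference_lookup


class AnnotationSource(Protocol):
    """On-demand per-annotator mask supplier (e.g. the simulator pool)."""

    @property
    def annotator_ids(self) -> Sequence[str]: ...

    def demographics_tag(self, annotator_id: str) -> str | None: ...

    def gold_references(self, kind: str) -> Sequence[ExpertReference]: ...

    def annotate(
        self, annotator_id: str, frame_id: str, structure: str
    ) -> BinaryMask: ...


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


class HoursSaved(NamedTuple):
    raw: float
    rounded: int


def expert_hours_saved(frames: int, seconds_per_frame: float) -> HoursSaved:
    """Expert hours avoided by crowdsourcing *frames* annotations."""
    if frames < 0:
        raise DomainError(f"frame count must be >= 0, got {frames}")
    if seconds_per_frame <= 0:
        raise DomainError(f"seconds per frame must be > 0, got {seconds_per_frame}")
    raw = frames * seconds_per_frame / 3600.0
    return HoursSaved(raw=raw, rounded=_round_half_up(raw))


def frames_per_expert_day(
    experts: int, hours_per_day: float, seconds_per_frame: float
) -> int:
    """Frames a bench of experts could annotate per day, rounded."""
    if experts <= 0 or hours_per_day <= 0 or seconds_per_frame <= 0:
        raise DomainError("experts, hours per day and seconds per frame must be > 0")
    return _round_half_up(experts * hours_per_day * 3600.0 / seconds_per_frame)


class TagShare(NamedTuple):
    count: int
    percent: int


def demographics_summary(
    profiles: Iterable[AnnotatorProfile],
) -> dict[str, TagShare]:
    """Per-tag counts with half-up integer percentages (untagged -> 'unknown')."""
    tags = [p.demographics_tag or "unknown" for p in profiles]
    total = len(tags)
    out: dict[str, TagShare] = {}
    for tag in sorted(set(tags)):
        count = tags.count(tag)
        out[tag] = TagShare(count=count, percent=_round_half_up(100.0 * count / total))
    return out


@dataclass(frozen=True)
class PendingTask:
    frame_id: str
    structure: str
    n_collected: int


@dataclass(frozen=True)
class CampaignLedger:
    frames: int
    structures: int
    individual_annotations: int
    consensus_annotations: int
    pending_tasks: int
    pending_annotations: int
    gold_training_annotations: int
    gold_running_annotations: int
    qa_flagged: int
    qa_sampled: int
    expert_hours_saved: float
    expert_hours_saved_rounded: int
    frames_per_expert_day: int

    @property
    def total_emitted(self) -> int:
        """Every annotation the source produced, regardless of fate."""
        return (
            self.individual_annotations
            + self.pending_annotations
            + self.gold_training_annotations
            + self.gold_running_annotations
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class CampaignResult:
    consensus_records: list[ConsensusRecord]
    difficulty_records: list[DifficultyRecord]
    profiles: dict[str, AnnotatorProfile]
    ledger: CampaignLedger
    pending: list[PendingTask] = field(default_factory=list)


def _train_pool(
    source: AnnotationSource, config: CampaignConfig
) -> tuple[dict[str, AnnotatorProfile], int]:
    gold = list(source.gold_references("training"))
    if len(gold) < config.n_training_gold:
        raise ConfigurationError(
            f"source provides {len(gold)} training gold tasks, "
            f"config requires {config.n_training_gold}"
        )
    gold = gold[: config.n_training_gold]
    refs = reference_lookup(gold)
    profiles: dict[str, AnnotatorProfile] = {}
    emitted = 0
    for aid in source.annotator_ids:
        anns = [
            Annotation(
                annotator_id=aid,
                frame_id=ref.frame_id,
                structure=ref.structure,
                mask=source.annotate(aid, ref.frame_id, ref.structure),
                role=Role.TRAINING_GOLD,
            )
            for ref in gold
        ]
        emitted += len(anns)
        profiles[aid] = score_training(
            aid, anns, refs, config,
            demographics_tag=source.demographics_tag(aid),
        )
    return profiles, emitted


def run_campaign(
    tasks: Sequence[tuple[str, str]],
    source: AnnotationSource,
    config: CampaignConfig,
) -> CampaignResult:
    """Run a whole campaign over *tasks* = (frame_id, structure) pairs.

    Deterministic under ``config.seed`` and the source's own seeding. Every
    completed task yields a consensus record and a QA-routed difficulty
    record; under-subscribed tasks are reported as pending, never raised.
    """
    for _, structure in tasks:
        config.structure_params(structure)  # fail fast on unknown structures

    rng = np.random.default_rng(config.seed)
    profiles, gold_training_n = _train_pool(source, config)
    running_pool = list(source.gold_references("running"))

    consensus_records: list[ConsensusRecord] = []
    difficulty_records: list[DifficultyRecord] = []
    pending: list[PendingTask] = []
    individual = 0
    stranded = 0
    gold_running_n = 0
    loads: dict[str, int] = {aid: 0 for aid in profiles}
    p_gold = 1.0 / config.rs_cadence

    order = rng.permutation(len(tasks))
    for ti in order:
        frame_id, structure = tasks[ti]
        params = config.structure_params(structure)
        collected: list[Annotation] = []
        tried: set[str] = set()
        while len(collected) < params.n_min:
            candidates = [
                aid for aid, prof in profiles.items()
                if prof.qualified and aid not in tried
            ]
            if not candidates:
                break
            candidates.sort(key=lambda aid: (loads[aid], aid))
            aid = candidates[0]
            tried.add(aid)
            # intermittent running-gold test before the ordinary task
            if running_pool and rng.random() < p_gold:
                ref = running_pool[int(rng.integers(len(running_pool)))]
                gold_ann = Annotation(
                    annotator_id=aid,
                    frame_id=ref.frame_id,
                    structure=ref.structure,
                    mask=source.annotate(aid, ref.frame_id, ref.structure),
                    role=Role.RUNNING_GOLD,
                )
                gold_running_n += 1
                profiles[aid] = update_running_score(
                    profiles[aid], gold_ann, ref, config.rs_window, config
                )
                if not profiles[aid].qualified:
                    continue  # prospective disqualification
            collected.append(
                Annotation(
                    annotator_id=aid,
                    frame_id=frame_id,
                    structure=structure,
                    mask=source.annotate(aid, frame_id, structure),
                )
            )
            loads[aid] += 1

        record = build_consensus(collected, config, structure)
        if record is None:
            pending.append(PendingTask(frame_id, structure, len(collected)))
            stranded += len(collected)
            continue
        individual += record.n_used
        consensus_records.append(record)
        by_id = {a.annotator_id: a.mask for a in collected}
        diff = make_record(
            frame_id, structure,
            [by_id[cid] for cid in record.contributor_ids],
            record.mask,
        )
        difficulty_records.append(
            flag_for_review(diff, config.rt, config.qa_sampling_rate, rng)
        )

    # stable output order (the routing permutation is an internal detail)
    consensus_records.sort(key=lambda r: (r.frame_id, r.structure))
    difficulty_records.sort(key=lambda r: (r.frame_id, r.structure))
    pending.sort(key=lambda p: (p.frame_id, p.structure))

    n_frames = len({f for f, _ in tasks})
    hours = expert_hours_saved(n_frames, config.expert_seconds_per_frame)
    ledger = CampaignLedger(
        frames=n_frames,
        structures=len({s for _, s in tasks}),
        individual_annotations=individual,
        consensus_annotations=len(consensus_records),
        pending_tasks=len(pending),
        pending_annotations=stranded,
        gold_training_annotations=gold_training_n,
        gold_running_annotations=gold_running_n,
        qa_flagged=sum(r.qa_flagged for r in difficulty_records),
        qa_sampled=sum(r.qa_sampled for r in difficulty_records),
        expert_hours_saved=hours.raw,
        expert_hours_saved_rounded=hours.rounded,
        frames_per_expert_day=frames_per_expert_day(
            config.experts_available,
            config.expert_hours_per_day,
            config.expert_seconds_per_frame,
        ),
    )
    return CampaignResult(
        consensus_records=consensus_records,
        difficulty_records=difficulty_records,
        profiles=profiles,
        ledger=ledger,
        pending=pending,
    )
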