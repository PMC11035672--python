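from __future__ import annotations

import numpy as np
import pytest
from pydantic import ValidationError

from crowdseg import (
    AnnotatorSpec,
    BinaryMask,
    SceneSpec,
    SimulatedPool,
    default_config,
    iou,
    make_ground_truth,
    run_campaign,
    simulate_annotation,
    uniform_pool,
)
from crowdseg.errors import ConfigurationError
from crowdseg.simulate import _stream

from oracles import JITTER2_NOISE05_IOU_BAND, oracle_jitter_annotation


def _disc_gt() -> BinaryMask:
    yy, xx = np.mgrid[:64, :64]
    return BinaryMask((yy - 32) ** 2 + (xx - 32) ** 2 <= 12 ** 2)


class TestGroundTruth:
    def test_presence_zero_always_empty(self):
        spec = SceneSpec(
            width=32, height=32,
            structures={"bowel": {"presence_probability": 0.0}},
        )
        for i in range(20):
            assert make_ground_truth(spec, i)["bowel"].is_empty

    def test_deterministic_under_seed_and_frame(self):
        spec = SceneSpec(
            width=32, height=32,
            structures={"bowel": {"presence_probability": 1.0, "blob_count": (1, 1), "blob_radius": (3, 3)}},
            seed=9,
        )
        a = make_ground_truth(spec, 4)["bowel"]
        b = make_ground_truth(spec, 4)["bowel"]
        assert a == b and not a.is_empty

    def test_presence_fraction_binomial(self):
        spec = SceneSpec(
            width=24, height=24,
            structures={"bowel": {"presence_probability": 0.7, "blob_radius": (2, 5)}},
            seed=3,
        )
        present = sum(
            not make_ground_truth(spec, i)["bowel"].is_empty for i in range(1000)
        )
        sigma = np.sqrt(1000 * 0.7 * 0.3)
        assert abs(present - 700) <= 3 * sigma

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValidationError):
            SceneSpec(
                width=10, height=10,
                structures={"bowel": {"blob_radius": (6, 8)}},
            )


class TestSimulateAnnotation:
    def test_perfect_annotator_is_identity(self, rng):
        gt = _disc_gt()
        spec = AnnotatorSpec(annotator_id="a")
        assert simulate_annotation(gt, spec, rng) == gt

    def test_always_miss_is_no_finding(self, rng):
        spec = AnnotatorSpec(annotator_id="a", miss_probability=1.0)
        assert simulate_annotation(_disc_gt(), spec, rng).is_empty

    def test_empty_truth_stays_empty_for_honest_annotators(self, rng):
        spec = AnnotatorSpec(annotator_id="a", boundary_jitter=3, pixel_noise=0.1)
        assert simulate_annotation(BinaryMask.empty(32, 32), spec, rng).is_empty

    def test_spammer_ignores_truth(self):
        spec = AnnotatorSpec(annotator_id="s", spammer=True)
        gt = _disc_gt()
        ious = [
            iou(simulate_annotation(gt, spec, np.random.default_rng(s)), gt)
            for s in range(50)
        ]
        assert np.mean(ious) < 0.3

    def test_matches_naive_morphology_oracle(self):
        # identical random stream -> identical mask, pixel for pixel
        gt = _disc_gt()
        spec = AnnotatorSpec(annotator_id="a", boundary_jitter=2, pixel_noise=0.05)
        for seed in range(20):
            got = simulate_annotation(gt, spec, np.random.default_rng(seed))
            want = oracle_jitter_annotation(
                gt.data.copy(), 2, 0.05, np.random.default_rng(seed)
            )
            assert np.array_equal(got.data, want)

    def test_mean_iou_in_preregistered_band(self):
        gt = _disc_gt()
        spec = AnnotatorSpec(annotator_id="a", boundary_jitter=2, pixel_noise=0.05)
        ious = [
            iou(simulate_annotation(gt, spec, np.random.default_rng(s)), gt)
            for s in range(500)
        ]
        lo, hi = JITTER2_NOISE05_IOU_BAND
        assert lo <= float(np.mean(ious)) <= hi


class TestSimulatedPool:
    def test_repeat_queries_identical(self, small_scene):
        pool = uniform_pool(5, small_scene, 5, seed=2)
        a = pool.annotate("ann_000", "frame_00001", "bowel")
        b = pool.annotate("ann_000", "frame_00001", "bowel")
        assert a == b

    def test_same_seed_identical_stream(self, small_scene):
        p1 = uniform_pool(5, small_scene, 5, seed=2)
        p2 = uniform_pool(5, small_scene, 5, seed=2)
        for fid, structure in p1.tasks:
            for aid in p1.annotator_ids:
                assert p1.annotate(aid, fid, structure) == p2.annotate(aid, fid, structure)

    def test_adding_annotators_preserves_streams(self, small_scene):
        p5 = uniform_pool(5, small_scene, 5, seed=2)
        p6 = uniform_pool(6, small_scene, 5, seed=2)
        assert p5.annotate("ann_001", "frame_00002", "bowel") == p6.annotate(
            "ann_001", "frame_00002", "bowel"
        )

    def test_gold_references_are_nontrivial(self, small_scene):
        pool = uniform_pool(5, small_scene, 5, seed=2)
        for kind in ("training", "running"):
            for ref in pool.gold_references(kind):
                assert not ref.mask.is_empty

    def test_unknown_ids_rejected(self, small_scene):
        pool = uniform_pool(5, small_scene, 5)
        with pytest.raises(ConfigurationError):
            pool.annotate("ghost", "frame_00000", "bowel")
        with pytest.raises(ConfigurationError):
            pool.annotate("ann_000", "frame_99999", "bowel")
        with pytest.raises(ConfigurationError):
            pool.gold_references("bronze")

    def test_perfect_pool_reproduces_ground_truth(self, small_scene):
        pool = uniform_pool(5, small_scene, 10, boundary_jitter=0, pixel_noise=0.0, seed=4)
        config = default_config(seed=4)
        result = run_campaign(pool.tasks, pool, config)
        assert result.ledger.pending_tasks == 0
        for rec in result.consensus_records:
            assert rec.mask == pool.ground_truth(rec.frame_id, rec.structure)
        assert all(r.di == 0.0 for r in result.difficulty_records)

    def test_single_spammer_cannot_break_mv4(self, small_scene):
        specs = [AnnotatorSpec(annotator_id=f"good_{i}") for i in range(4)]
        specs.append(AnnotatorSpec(annotator_id="spam", spammer=True))
        pool = SimulatedPool(specs, small_scene, 10, seed=6)
        # disable gating so the spammer contributes, then rely on mv=4
        config = default_config(ts_min=0.0, rs_min=0.0, seed=6)
        result = run_campaign(
            [(f, s) for f, s in pool.tasks if s == "bowel"], pool, config
        )
        for rec in result.consensus_records:
            assert rec.mask == pool.ground_truth(rec.frame_id, rec.structure)


class TestHierarchicalStreams:
    def test_stream_keys_are_independent(self):
        a = _stream(1, "x", "f1").random(4)
        b = _stream(1, "x", "f2").random(4)
        c = _stream(1, "x", "f1").random(4)
        assert not np.allclose(a, b)
        assert np.allclose(a, c)

    def test_jitter_monotonically_degrades_median_di(self, small_scene):
        from crowdseg.consensus import majority_vote
        from crowdseg.difficulty import difficulty_index

        medians = []
        for jitter in (0, 1, 2, 4):
            dis = []
            for frame in range(40):
                gt = make_ground_truth(small_scene, frame, force_presence=True)["bowel"]
                spec = AnnotatorSpec(annotator_id="a", boundary_jitter=jitter)
                masks = [
                    simulate_annotation(gt, spec, np.random.default_rng((jitter + 1) * 1000 + frame * 10 + k))
                    for k in range(5)
                ]
                dis.append(difficulty_index(masks, majority_vote(masks, 3)))
            medians.append(float(np.median(dis)))
        assert medians == sorted(medians)
        assert medians[0] < medians[-1]
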