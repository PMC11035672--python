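"""Synthetic scenes and skill-parameterized synthetic annotators.

Nothing here models real surgical imagery; the simulator exists so that
every pipeline stage — gating, consensus, difficulty, ledger — can be
exercised end-to-end against a known ground truth. Scenes are unions of
random discs per structure, absent with a configurable probability (an
absent structure yields the empty "no finding" ground truth). Annotators
perturb the truth with symmetric morphological boundary jitter, random
boundary-pixel flips, a miss probability ("no finding" despite a visible
structure), or ignore the truth entirely (spammers).

Random streams are derived hierarchically from
``(seed, annotator_id, frame_id, structure)`` so that adding annotators or
frames never perturbs existing streams, and repeated queries for the same
task return the identical mask.
"""

from __future__ import annotations

import zlib
from typing import Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from skimage.draw import disk as draw_disk
from skimage.morphology import dilation, disk as disk_footprint, erosion

from .errors import ConfigurationError
from .masks import BinaryMask, ExpertReference

_TRAINING_GOLD_KIND = "training"
_RUNNING_GOLD_KIND = "running"


def _stream(*keys: int | str) -> np.random.Generator:
    """Deterministic generator keyed by a mixed int/str tuple."""
    entropy = [
        k & 0xFFFFFFFF if isinstance(k, int) else zlib.crc32(k.encode("utf-8"))
        for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


class StructureScene(BaseModel):
    """How one structure appears in synthetic frames."""

    model_config = ConfigDict(frozen=True)

    presence_probability: float = Field(default=1.0, ge=0.0, le=1.0)
    blob_count: tuple[int, int] = (1, 2)
    blob_radius: tuple[int, int] = (4, 10)

    @model_validator(mode="after")
    def _check_ranges(self) -> "StructureScene":
        if self.blob_count[0] < 1 or self.blob_count[0] > self.blob_count[1]:
            raise ValueError(f"bad blob_count range {self.blob_count}")
        if self.blob_radius[0] < 1 or self.blob_radius[0] > self.blob_radius[1]:
            raise ValueError(f"bad blob_radius range {self.blob_radius}")
        return self


class SceneSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    width: int = Field(ge=1)
    height: int = Field(ge=1)
    structures: dict[str, StructureScene]
    seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "SceneSpec":
        if not self.structures:
            raise ValueError("scene needs at least one structure")
        for label, sc in self.structures.items():
            if 2 * sc.blob_radius[1] > min(self.width, self.height):
                raise ValueError(
                    f"{label}: blob radius {sc.blob_radius[1]} does not fit "
                    f"a {self.height}x{self.width} frame"
                )
        return self


class AnnotatorSpec(BaseModel):
    """Error model of one synthetic annotator."""

    model_config = ConfigDict(frozen=True)

    annotator_id: str
    #: max radius (px) of random morphological dilation/erosion of the truth
    boundary_jitter: int = Field(default=0, ge=0)
    #: flip rate for pixels in the 1-px boundary band
    pixel_noise: float = Field(default=0.0, ge=0.0, le=1.0)
    #: probability of submitting "no finding" despite a visible structure
    miss_probability: float = Field(default=0.0, ge=0.0, le=1.0)
    #: ignore the ground truth entirely (random blob or empty mask)
    spammer: bool = False
    mean_delay_s: float = Field(default=30.0, gt=0.0)
    demographics_tag: str | None = None


def _random_blobs(
    rng: np.random.Generator, height: int, width: int, scene: StructureScene
) -> np.ndarray:
    arr = np.zeros((height, width), dtype=bool)
    n_blobs = int(rng.integers(scene.blob_count[0], scene.blob_count[1] + 1))
    for _ in range(n_blobs):
        radius = int(rng.integers(scene.blob_radius[0], scene.blob_radius[1] + 1))
        r = int(rng.integers(radius, height - radius)) if height > 2 * radius else height // 2
        c = int(rng.integers(radius, width - radius)) if width > 2 * radius else width // 2
        rr, cc = draw_disk((r, c), radius, shape=(height, width))
        arr[rr, cc] = True
    return arr


def make_ground_truth(
    spec: SceneSpec, frame_index: int, force_presence: bool = False
) -> dict[str, BinaryMask]:
    """Per-structure ground-truth masks for one frame.

    With probability ``presence_probability`` the structure is a union of
    random discs, otherwise empty. Deterministic under
    ``(spec.seed, frame_index, structure)``. *force_presence* overrides the
    absence draw (used for gold frames, which must be non-trivial).
    """
    masks: dict[str, BinaryMask] = {}
    for label, scene in spec.structures.items():
        rng = _stream(spec.seed, frame_index, label)
        present = force_presence or rng.random() < scene.presence_probability
        if present:
            masks[label] = BinaryMask(
                _random_blobs(rng, spec.height, spec.width, scene)
            )
        else:
            masks[label] = BinaryMask.empty(spec.height, spec.width)
    return masks


def _boundary_band(arr: np.ndarray) -> np.ndarray:
    fp = disk_footprint(1)
    return dilation(arr, fp) & ~erosion(arr, fp)


def simulate_annotation(
    gt: BinaryMask, spec: AnnotatorSpec, rng: np.random.Generator
) -> BinaryMask:
    """One synthetic annotation of *gt* under the annotator's error model.

    Spammers submit a random disc (or, occasionally, "no finding") that
    ignores the truth. Honest annotators may miss (empty mask), otherwise
    the truth is dilated or eroded by a disc of radius drawn uniformly from
    ``{-jitter, ..., +jitter}`` (negative = erosion) and pixels in the 1-px
    boundary band are flipped at the pixel-noise rate.
    """
    h, w = gt.shape
    if spec.spammer:
        if rng.random() < 0.2:
            return BinaryMask.empty(h, w)
        scene = StructureScene(blob_radius=(2, max(2, min(h, w) // 3)))
        return BinaryMask(_random_blobs(rng, h, w, scene))
    if rng.random() < spec.miss_probability:
        return BinaryMask.empty(h, w)
    arr = np.asarray(gt.data)
    if spec.boundary_jitter > 0:
        radius = int(rng.integers(-spec.boundary_jitter, spec.boundary_jitter + 1))
        if radius > 0:
            arr = dilation(arr, disk_footprint(radius))
        elif radius < 0:
            arr = erosion(arr, disk_footprint(-radius))
    if spec.pixel_noise > 0.0:
        band = _boundary_band(arr)
        flips = band & (rng.random((h, w)) < spec.pixel_noise)
        arr = arr ^ flips
    return BinaryMask(arr)


class SimulatedPool:
    """An on-demand annotation source backed by the synthetic scene model.

    Implements the annotation-source contract consumed by
    :func:`crowdseg.campaign.run_campaign`: stable annotator ids, gold
    reference pools (training and running), and per-task ``annotate``
    queries. Gold frames live outside the ordinary frame index range and
    always contain the structure (an all-empty gold reference could not
    discriminate skill).
    """

    def __init__(
        self,
        annotators: Sequence[AnnotatorSpec],
        scene: SceneSpec,
        n_frames: int,
        n_gold_training: int = 10,
        n_gold_running: int = 20,
        seed: int = 0,
    ) -> None:
        if not annotators:
            raise ConfigurationError("annotator pool is empty")
        ids = [a.annotator_id for a in annotators]
        if len(ids) != len(set(ids)):
            raise ConfigurationError("duplicate annotator ids in pool")
        self.annotators = {a.annotator_id: a for a in annotators}
        self.scene = scene
        self.n_frames = n_frames
        self.seed = seed
        self.frame_ids = [f"frame_{i:05d}" for i in range(n_frames)]
        self._frame_index = {fid: i for i, fid in enumerate(self.frame_ids)}

        structures = list(scene.structures)
        self._gold: dict[str, list[ExpertReference]] = {}
        offset = n_frames
        for kind, count in (
            (_TRAINING_GOLD_KIND, n_gold_training),
            (_RUNNING_GOLD_KIND, n_gold_running),
        ):
            refs = []
            for j in range(count):
                structure = structures[j % len(structures)]
                fid = f"gold_{kind}_{j:03d}"
                idx = offset + j
                self._frame_index[fid] = idx
                gt = make_ground_truth(scene, idx, force_presence=True)[structure]
                refs.append(
                    ExpertReference(
                        frame_id=fid, structure=structure, mask=gt,
                        expert_id="sim_expert",
                    )
                )
            self._gold[kind] = refs
            offset += count

    # -- annotation-source contract ----------------------------------------
    @property
    def annotator_ids(self) -> list[str]:
        return list(self.annotators)

    def demographics_tag(self, annotator_id: str) -> str | None:
        return self.annotators[annotator_id].demographics_tag

    def gold_references(self, kind: str) -> list[ExpertReference]:
        if kind not in self._gold:
            raise ConfigurationError(f"unknown gold pool {kind!r}")
        return list(self._gold[kind])

    @property
    def tasks(self) -> list[tuple[str, str]]:
        """All ordinary (frame_id, structure) tasks, frame-major order."""
        return [
            (fid, structure)
            for fid in self.frame_ids
            for structure in self.scene.structures
        ]

    def ground_truth(self, frame_id: str, structure: str) -> BinaryMask:
        try:
            idx = self._frame_index[frame_id]
        except KeyError:
            raise ConfigurationError(f"unknown frame {frame_id!r}") from None
        force = not frame_id.startswith("frame_")
        return make_ground_truth(self.scene, idx, force_presence=force)[structure]

    def annotate(self, annotator_id: str, frame_id: str, structure: str) -> BinaryMask:
        """The annotator's mask for one task; identical on repeated calls."""
        try:
            spec = self.annotators[annotator_id]
        except KeyError:
            raise ConfigurationError(f"unknown annotator {annotator_id!r}") from None
        gt = self.ground_truth(frame_id, structure)
        rng = _stream(self.seed, annotator_id, frame_id, structure)
        return simulate_annotation(gt, spec, rng)

    def elapsed(self, annotator_id: str, frame_id: str, structure: str) -> float:
        """Simulated annotation time (exponential around the mean delay)."""
        spec = self.annotators[annotator_id]
        rng = _stream(self.seed, annotator_id, frame_id, structure, "delay")
        return float(rng.exponential(spec.mean_delay_s))


def uniform_pool(
    n_annotators: int,
    scene: SceneSpec,
    n_frames: int,
    boundary_jitter: int = 1,
    pixel_noise: float = 0.02,
    miss_probability: float = 0.0,
    n_spammers: int = 0,
    seed: int = 0,
    **pool_kwargs,
) -> SimulatedPool:
    """Convenience constructor: n identical honest annotators + spammers."""
    specs = [
        AnnotatorSpec(
            annotator_id=f"ann_{i:03d}",
            boundary_jitter=boundary_jitter,
            pixel_noise=pixel_noise,
            miss_probability=miss_probability,
        )
        for i in range(n_annotators)
    ]
    specs += [
        AnnotatorSpec(annotator_id=f"spam_{i:03d}", spammer=True)
        for i in range(n_spammers)
    ]
    return SimulatedPool(specs, scene, n_frames, seed=seed, **pool_kwargs)
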