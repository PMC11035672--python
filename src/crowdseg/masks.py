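"""Binary mask data model and raster/manifest I/O.

Conventions (used everywhere in the package):

* coordinates are 0-based ``(row, col)``, row-major, origin at the top-left;
* masks are stored on disk as single-channel 8-bit PNG, 0 = background,
  255 = foreground; on read, any pixel value >= 128 is foreground;
* an empty foreground is a valid mask and denotes the "no finding"
  annotation;
* manifests are UTF-8 CSV files with a header row, mask paths relative to
  the manifest's own directory.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import ComparabilityError, ManifestSchemaError, MaskFormatError

#: pixel values at or above this are foreground when reading rasters
BINARIZATION_THRESHOLD = 128

MANIFEST_COLUMNS = ("annotator_id", "frame_id", "structure", "role", "mask_path")
REFERENCE_COLUMNS = ("frame_id", "structure", "expert_id", "mask_path")


class Role(str, enum.Enum):
    """Role of an annotation within a campaign."""

    ORDINARY = "ordinary"
    TRAINING_GOLD = "training_gold"
    RUNNING_GOLD = "running_gold"

    @property
    def is_gold(self) -> bool:
        return self is not Role.ORDINARY


@dataclass(frozen=True)
class BinaryMask:
    """A frame-sized binary pixel labelling for a single structure.

    Backed by a read-only 2-D boolean array. Two masks are comparable only
    when their dimensions match; use :meth:`require_comparable` before any
    pixel-wise operation.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 2:
            raise MaskFormatError(f"mask array must be 2-D, got shape {arr.shape}")
        arr = arr.astype(bool, copy=True)
        arr.setflags(write=False)
        object.__setattr__(self, "data", arr)

    # -- geometry -----------------------------------------------------------
    @property
    def height(self) -> int:
        return int(self.data.shape[0])

    @property
    def width(self) -> int:
        return int(self.data.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_pixels(self) -> int:
        return self.height * self.width

    # -- content ------------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        """True for the "no finding" annotation."""
        return not bool(self.data.any())

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    @property
    def foreground(self) -> frozenset[tuple[int, int]]:
        """Foreground pixel coordinates as a set of ``(row, col)`` tuples."""
        rows, cols = np.nonzero(self.data)
        return frozenset(zip(rows.tolist(), cols.tolist()))

    # -- construction -------------------------------------------------------
    @classmethod
    def empty(cls, height: int, width: int) -> "BinaryMask":
        return cls(np.zeros((height, width), dtype=bool))

    @classmethod
    def from_pixels(
        cls, height: int, width: int, pixels: Iterable[tuple[int, int]]
    ) -> "BinaryMask":
        arr = np.zeros((height, width), dtype=bool)
        for r, c in pixels:
            if not (0 <= r < height and 0 <= c < width):
                raise MaskFormatError(
                    f"pixel ({r}, {c}) outside {height}x{width} frame"
                )
            arr[r, c] = True
        return cls(arr)

    # -- comparison ---------------------------------------------------------
    def require_comparable(self, other: "BinaryMask") -> None:
        if self.shape != other.shape:
            raise ComparabilityError(
                f"mask dimensions differ: {self.shape} vs {other.shape}"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMask):
            return NotImplemented
        return self.shape == other.shape and bool(np.array_equal(self.data, other.data))

    def __hash__(self) -> int:
        return hash((self.shape, self.data.tobytes()))


@dataclass(frozen=True)
class Annotation:
    """One annotator's mask for one (frame, structure) task."""

    annotator_id: str
    frame_id: str
    structure: str
    mask: BinaryMask
    role: Role = Role.ORDINARY
    elapsed_s: float | None = None

    @property
    def task(self) -> tuple[str, str]:
        return (self.frame_id, self.structure)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.annotator_id, self.frame_id, self.structure)


@dataclass(frozen=True)
class ExpertReference:
    """An expert gold-standard mask used to score annotators."""

    frame_id: str
    structure: str
    mask: BinaryMask
    expert_id: str = "expert"

    @property
    def task(self) -> tuple[str, str]:
        return (self.frame_id, self.structure)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a single-channel raster into a :class:`BinaryMask`.

    Pixels with value >= :data:`BINARIZATION_THRESHOLD` become foreground.
    """
    path = Path(path)
    try:
        with Image.open(path) as img:
            if img.mode not in ("L", "1", "I", "I;16"):
                raise MaskFormatError(
                    f"{path}: expected single-channel mask, got mode {img.mode!r}"
                )
            arr = np.asarray(img)
    except (UnidentifiedImageError, OSError) as exc:
        if isinstance(exc, MaskFormatError):
            raise
        raise OSError(f"cannot read mask file {path}: {exc}") from exc
    if arr.dtype == bool:
        return BinaryMask(arr)
    return BinaryMask(arr >= BINARIZATION_THRESHOLD)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write *mask* as an 8-bit PNG (0 background, 255 foreground)."""
    path = Path(path)
    img = Image.fromarray(np.where(mask.data, 255, 0).astype(np.uint8), mode="L")
    try:
        img.save(path, format="PNG")
    except OSError as exc:
        raise OSError(f"cannot write mask file {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ManifestSchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _resolve_mask_paths(df: pd.DataFrame, base: Path) -> list[Path]:
    paths = [base / p for p in df["mask_path"].astype(str)]
    dangling = [str(p) for p in paths if not p.is_file()]
    if dangling:
        raise FileNotFoundError(
            "manifest references missing mask file(s): " + ", ".join(dangling)
        )
    return paths


def load_manifest(
    manifest_path: str | Path,
    references_path: str | Path | None = None,
) -> tuple[list[Annotation], list[ExpertReference]]:
    """Load annotations (and, optionally, expert references) from CSV.

    Annotation manifest columns: ``annotator_id, frame_id, structure, role,
    mask_path`` (``elapsed_s`` optional). Reference table columns:
    ``frame_id, structure, expert_id, mask_path``. Paths are resolved
    relative to each table's location.

    Raises :class:`ManifestSchemaError` on a missing column, an unknown
    role, or a duplicated ``(annotator_id, frame_id, structure)`` key, and
    :class:`FileNotFoundError` listing every dangling mask path.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    _require_columns(df, MANIFEST_COLUMNS, manifest_path)

    keys = list(zip(df["annotator_id"], df["frame_id"], df["structure"]))
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1})
        raise ManifestSchemaError(
            f"{manifest_path}: duplicate (annotator_id, frame_id, structure) "
            f"rows: {dupes}"
        )

    annotations: list[Annotation] = []
    if len(df):
        paths = _resolve_mask_paths(df, manifest_path.parent)
        for (_, row), mask_file in zip(df.iterrows(), paths):
            try:
                role = Role(row["role"])
            except ValueError:
                raise ManifestSchemaError(
                    f"{manifest_path}: unknown role {row['role']!r}"
                ) from None
            elapsed = row.get("elapsed_s", "")
            annotations.append(
                Annotation(
                    annotator_id=row["annotator_id"],
                    frame_id=row["frame_id"],
                    structure=row["structure"],
                    mask=read_mask(mask_file),
                    role=role,
                    elapsed_s=float(elapsed) if elapsed not in ("", None) else None,
                )
            )

    references: list[ExpertReference] = []
    if references_path is not None:
        references = load_references(references_path)
        ref_tasks = {r.task for r in references}
        for ann in annotations:
            if ann.role.is_gold and ann.task not in ref_tasks:
                raise ManifestSchemaError(
                    f"gold annotation {ann.key} has no expert reference for "
                    f"task {ann.task}"
                )

    return annotations, references


def load_references(path: str | Path) -> list[ExpertReference]:
    """Load an expert-reference table (see :func:`load_manifest`)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, REFERENCE_COLUMNS, path)
    keys = list(zip(df["frame_id"], df["structure"], df["expert_id"]))
    if len(keys) != len(set(keys)):
        raise ManifestSchemaError(
            f"{path}: duplicate (frame_id, structure, expert_id) rows"
        )
    refs: list[ExpertReference] = []
    if len(df):
        paths = _resolve_mask_paths(df, path.parent)
        for (_, row), mask_file in zip(df.iterrows(), paths):
            refs.append(
                ExpertReference(
                    frame_id=row["frame_id"],
                    structure=row["structure"],
                    mask=read_mask(mask_file),
                    expert_id=row["expert_id"],
                )
            )
    return refs


def write_manifest(annotations: Sequence[Annotation], path: str | Path,
                   mask_dir: str | Path | None = None) -> None:
    """Write annotations + masks next to a manifest CSV at *path*.

    Masks go under *mask_dir* (default: ``masks/`` beside the manifest) and
    the manifest stores paths relative to its own directory.
    """
    path = Path(path)
    base = path.parent
    mask_dir = Path(mask_dir) if mask_dir is not None else base / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ann in annotations:
        fname = f"{ann.annotator_id}__{ann.frame_id}__{ann.structure}.png"
        write_mask(ann.mask, mask_dir / fname)
        rows.append(
            {
                "annotator_id": ann.annotator_id,
                "frame_id": ann.frame_id,
                "structure": ann.structure,
                "role": ann.role.value,
                "mask_path": str((mask_dir / fname).relative_to(base)),
                "elapsed_s": "" if ann.elapsed_s is None else ann.elapsed_s,
            }
        )
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS) + ["elapsed_s"]).to_csv(
        path, index=False
    )


def write_references(references: Sequence[ExpertReference], path: str | Path,
                     mask_dir: str | Path | None = None) -> None:
    """Write expert references + masks next to a reference CSV at *path*."""
    path = Path(path)
    base = path.parent
    mask_dir = Path(mask_dir) if mask_dir is not None else base / "ref_masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ref in references:
        fname = f"{ref.expert_id}__{ref.frame_id}__{ref.structure}.png"
        write_mask(ref.mask, mask_dir / fname)
        rows.append(
            {
                "frame_id": ref.frame_id,
                "structure": ref.structure,
                "expert_id": ref.expert_id,
                "mask_path": str((mask_dir / fname).relative_to(base)),
            }
        )
    pd.DataFrame(rows, columns=list(REFERENCE_COLUMNS)).to_csv(path, index=False)


def reference_lookup(
    references: Iterable[ExpertReference],
) -> Mapping[tuple[str, str], ExpertReference]:
    """Index references by (frame_id, structure), first expert wins."""
    table: dict[tuple[str, str], ExpertReference] = {}
    for ref in references:
        table.setdefault(ref.task, ref)
    return table
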