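"""NIfTI ingestion, subject validation, normalization, cohort splitting.

Subject-level data lives in one directory per subject containing six NIfTI
files: the T1, T2 and FLAIR volumes plus one lesion mask per modality.  The
FLAIR grid is the reference grid: T1/T2 are resampled onto it with linear
interpolation, the FLAIR-space mask (nearest-neighbour resampled if needed)
serves as the single ground truth.

Intensities are z-scored per modality over the *non-zero* voxels only, so the
zero background of skull-stripped scans does not dilute the brain statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

#: canonical modality/mask roles of a subject directory
SUBJECT_ROLES = ("t1", "t2", "flair", "t1_mask", "t2_mask", "flair_mask")

#: default filename pattern per role (configurable in :func:`validate_subject`)
DEFAULT_PATTERNS: Mapping[str, str] = {
    "t1": "T1.nii.gz",
    "t2": "T2.nii.gz",
    "flair": "FLAIR.nii.gz",
    "t1_mask": "T1_mask.nii.gz",
    "t2_mask": "T2_mask.nii.gz",
    "flair_mask": "FLAIR_mask.nii.gz",
}


class SubjectValidationError(ValueError):
    """A subject directory is missing or has unreadable modality files."""


@dataclass(frozen=True)
class VolumeGrid:
    """A scalar 3-D image on a regular grid.

    Parameters
    ----------
    data
        3-D array of voxel intensities (finite).
    spacing
        Voxel edge length per axis in millimetres, strictly positive.
    orientation_tag
        Axis-order label after canonicalization ("RAS" once loaded).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    orientation_tag: str = "RAS"

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"expected a non-empty 3-D array, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive numbers, got {self.spacing}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class MultiModalVolume:
    """Channel-stacked (T1, T2, FLAIR) volume of shape ``[3, D, H, W]``."""

    channels: np.ndarray
    spacing: tuple[float, float, float]

    MODALITIES = ("t1", "t2", "flair")

    def __post_init__(self) -> None:
        channels = np.asarray(self.channels)
        if channels.ndim != 4 or channels.shape[0] != 3:
            raise ValueError(f"expected [3, D, H, W] channels, got shape {channels.shape}")
        object.__setattr__(self, "channels", channels)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.channels.shape[1:])  # type: ignore[return-value]


@dataclass(frozen=True)
class BinaryMask:
    """A {0,1} lesion label grid aligned to a :class:`MultiModalVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        values = np.unique(data)
        if not np.all(np.isin(values, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, found {values[:10]}")
        object.__setattr__(self, "data", data.astype(np.uint8))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]


@dataclass(frozen=True)
class SubjectRecord:
    """Resolved file paths of one validated subject directory."""

    subject_id: str
    paths: Mapping[str, Path]

    def __post_init__(self) -> None:
        missing = [r for r in SUBJECT_ROLES if r not in self.paths]
        if missing:
            raise ValueError(f"record missing roles: {missing}")


@dataclass(frozen=True)
class CohortSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        groups = (set(self.train_ids), set(self.val_ids), set(self.test_ids))
        total = sum(len(g) for g in groups)
        if len(groups[0] | groups[1] | groups[2]) != total:
            raise ValueError("split groups overlap (patient leakage)")


@dataclass(frozen=True)
class CohortStats:
    total_lesion_voxels: int
    total_voxels: int
    lesion_ratio_percent: float


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path: str | Path) -> VolumeGrid:
    """Load a NIfTI file and canonicalize its axes to closest-to-RAS order.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    SubjectValidationError
        If the file cannot be parsed as NIfTI.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
        img = nib.as_closest_canonical(img)
        data = np.asanyarray(img.dataobj)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # nibabel raises a zoo of error types
        raise SubjectValidationError(f"cannot parse NIfTI file {path}: {exc}") from exc
    return VolumeGrid(data=np.ascontiguousarray(data), spacing=spacing)


def write_nifti(grid: VolumeGrid, path: str | Path, dtype=np.float32) -> Path:
    """Write a :class:`VolumeGrid` (or compatible) to ``path`` with an RAS affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(grid.spacing) + [1.0])
    data = np.asarray(grid.data, dtype=dtype)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))
    return path


def validate_subject(
    directory: str | Path, patterns: Mapping[str, str] = DEFAULT_PATTERNS
) -> SubjectRecord:
    """Check that a subject directory holds all six modality/mask files.

    Every file must exist and parse as NIfTI; a failure lists *all* missing
    or unreadable roles so the subject can be reported rather than silently
    dropped.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise SubjectValidationError(f"subject directory does not exist: {directory}")
    paths: dict[str, Path] = {}
    problems: list[str] = []
    for role in SUBJECT_ROLES:
        candidate = directory / patterns[role]
        if not candidate.exists():
            # accept uncompressed twin of the default pattern
            alt = candidate.with_suffix("") if candidate.suffix == ".gz" else None
            if alt is not None and alt.exists():
                candidate = alt
            else:
                problems.append(f"{role} ({patterns[role]})")
                continue
        try:
            nib.load(str(candidate))
        except Exception:
            problems.append(f"{role} (unreadable: {candidate.name})")
            continue
        paths[role] = candidate
    if problems:
        raise SubjectValidationError(
            f"subject {directory.name}: missing or unreadable files: {', '.join(problems)}"
        )
    return SubjectRecord(subject_id=directory.name, paths=paths)


def validate_cohort(root: str | Path, patterns=DEFAULT_PATTERNS):
    """Validate all subject sub-directories under ``root``.

    Returns ``(records, failures)`` where failures maps subject id to the
    validation message — failing subjects are reported, never silently lost.
    """
    root = Path(root)
    records: list[SubjectRecord] = []
    failures: dict[str, str] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        try:
            records.append(validate_subject(sub, patterns))
        except SubjectValidationError as exc:
            failures[sub.name] = str(exc)
            logger.warning("excluding subject %s: %s", sub.name, exc)
    return records, failures


# ---------------------------------------------------------------------------
# Geometry and intensity
# ---------------------------------------------------------------------------

def resample_like(
    moving: VolumeGrid, reference: VolumeGrid, interpolation: str = "linear"
) -> VolumeGrid:
    """Resample ``moving`` onto the grid shape of ``reference``.

    Corner-aligned coordinate mapping; ``linear`` (order-1) interpolation for
    intensity volumes, ``nearest`` (order-0) for binary masks so label values
    stay in {0, 1}.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation mode: {interpolation!r}")
    if moving.shape == reference.shape:
        return VolumeGrid(moving.data.copy(), reference.spacing)
    order = 1 if interpolation == "linear" else 0
    axes_coords = []
    for n_in, n_out in zip(moving.shape, reference.shape):
        if n_out == 1:
            axes_coords.append(np.array([(n_in - 1) / 2.0]))
        else:
            axes_coords.append(np.linspace(0.0, n_in - 1.0, n_out))
    grid = np.meshgrid(*axes_coords, indexing="ij")
    out = ndimage.map_coordinates(
        moving.data.astype(np.float64), np.stack(grid), order=order, mode="nearest"
    )
    return VolumeGrid(out.astype(moving.data.dtype, copy=False), reference.spacing)


def zscore_normalize(
    grid: VolumeGrid, eps: float = 1e-8, preserve_zero_background: bool = False
) -> VolumeGrid:
    """Z-score a volume over its non-zero voxels: ``(I - mu) / (sigma + eps)``.

    ``mu`` and ``sigma`` (population, 1/N) are computed over non-zero voxels
    only.  By default the zero background passes through the same affine map;
    with ``preserve_zero_background`` it is pinned back to 0.  An all-zero
    volume is returned unchanged with a warning.
    """
    data = grid.data.astype(np.float64)
    nz = data != 0
    if not nz.any():
        logger.warning("zscore_normalize: all-zero volume, returned unchanged")
        return VolumeGrid(np.zeros_like(data, dtype=np.float32), grid.spacing)
    mu = float(data[nz].mean())
    sigma = float(data[nz].std())  # population (ddof=0)
    out = (data - mu) / (sigma + eps)
    if preserve_zero_background:
        out[~nz] = 0.0
    return VolumeGrid(out.astype(np.float32), grid.spacing)


def normalize_volume(volume: MultiModalVolume, eps: float = 1e-8, **kw) -> MultiModalVolume:
    """Apply :func:`zscore_normalize` independently per modality channel."""
    channels = np.stack(
        [
            zscore_normalize(VolumeGrid(c, volume.spacing), eps=eps, **kw).data
            for c in volume.channels
        ]
    )
    return MultiModalVolume(channels=channels, spacing=volume.spacing)


def binarize(grid: VolumeGrid, threshold: float = 0.5) -> BinaryMask:
    """Threshold a grid into a binary mask: strictly greater than ``threshold``."""
    return BinaryMask(data=(grid.data > threshold).astype(np.uint8), spacing=grid.spacing)


def load_subject(
    record: SubjectRecord, normalize: bool = True, eps: float = 1e-8
) -> tuple[MultiModalVolume, BinaryMask]:
    """Load a subject: T1/T2 resampled onto the FLAIR grid, FLAIR-space mask.

    The FLAIR volume defines the reference grid; the FLAIR-modality mask is
    the ground truth, binarized at 0.5 (nearest-neighbour resampled if its
    grid differs).
    """
    flair = read_nifti(record.paths["flair"])
    t1 = resample_like(read_nifti(record.paths["t1"]), flair, "linear")
    t2 = resample_like(read_nifti(record.paths["t2"]), flair, "linear")
    mask_grid = read_nifti(record.paths["flair_mask"])
    if mask_grid.shape != flair.shape:
        mask_grid = resample_like(mask_grid, flair, "nearest")
    volume = MultiModalVolume(
        channels=np.stack([t1.data, t2.data, flair.data]).astype(np.float32),
        spacing=flair.spacing,
    )
    if normalize:
        volume = normalize_volume(volume, eps=eps)
    return volume, binarize(mask_grid)


# ---------------------------------------------------------------------------
# Cohort-level operations
# ---------------------------------------------------------------------------

def split_cohort(
    ids: Sequence[str],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> CohortSplit:
    """Patient-level 70/15/15 split with a fixed random seed.

    Ids are shuffled by the seed, then assigned contiguously with
    floor-and-remainder rounding: ``train = floor(f_train * n)``,
    ``val = floor(f_val * n)``, test takes the remainder — exhaustive and
    disjoint by construction, so no patient leaks across subsets.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("subject ids must be unique")
    if len(ids) < 3:
        raise ValueError(f"need at least 3 ids to split, got {len(ids)}")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    shuffled = [ids[i] for i in order]
    n = len(ids)
    n_train = int(math.floor(fractions[0] * n))
    n_val = int(math.floor(fractions[1] * n))
    return CohortSplit(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train : n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val :]),
        seed=seed,
    )


def write_split_manifest(split: CohortSplit, path: str | Path) -> Path:
    """Persist a split as a plain-text table (subject_id, split) plus the seed."""
    rows = (
        [(i, "train") for i in split.train_ids]
        + [(i, "val") for i in split.val_ids]
        + [(i, "test") for i in split.test_ids]
    )
    frame = pd.DataFrame(rows, columns=["subject_id", "split"])
    frame["seed"] = split.seed
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False)
    return path


def read_split_manifest(path: str | Path) -> CohortSplit:
    frame = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    by = {k: tuple(g["subject_id"]) for k, g in frame.groupby("split", sort=False)}
    return CohortSplit(
        train_ids=by.get("train", ()),
        val_ids=by.get("val", ()),
        test_ids=by.get("test", ()),
        seed=int(frame["seed"].iloc[0]),
    )


def lesion_ratio(masks: Iterable[BinaryMask]) -> CohortStats:
    """Pooled global lesion ratio, in percent: ``100 * lesion voxels / voxels``."""
    lesion = 0
    total = 0
    for mask in masks:
        lesion += int(mask.data.sum())
        total += int(mask.data.size)
    if total == 0:
        raise ValueError("lesion_ratio requires at least one mask")
    return CohortStats(
        total_lesion_voxels=lesion,
        total_voxels=total,
        lesion_ratio_percent=100.0 * lesion / total,
    )
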