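"""Synthetic multi-modal MS-like phantom cohorts.

Each phantom subject is an ellipsoidal "brain" of constant per-modality tissue
intensity inside a zero background, seeded with randomly placed ellipsoidal
lesions until a target voxel prevalence is reached.  Lesions follow the MS
contrast convention — hyperintense on FLAIR and T2, mildly hypointense on T1 —
and the rendered volumes are degraded by a smooth multiplicative bias field and
additive Gaussian noise inside the brain.

The generator's defaults emulate the summary statistics of a consensus-annotated
60-subject MS cohort: sparse (~0.29% of voxels), scattered, anisotropic lesions
on a 96^3 grid sized so that several training patches fit on CPU in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    BinaryMask,
    MultiModalVolume,
    SubjectRecord,
    VolumeGrid,
    validate_subject,
    write_nifti,
)

#: per-modality {background, brain, lesion} intensity means (arbitrary units);
#: FLAIR/T2 lesions hyperintense, T1 lesions mildly hypointense.
DEFAULT_TISSUE_MEANS: Mapping[str, tuple[float, float, float]] = {
    "t1": (0.0, 1.0, 0.85),
    "t2": (0.0, 0.60, 1.10),
    "flair": (0.0, 0.70, 1.25),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters of one synthetic subject (or a cohort of them)."""

    shape: tuple[int, int, int] = (96, 96, 96)
    target_prevalence: float = 0.0029
    n_lesions_range: tuple[int, int] = (1, 60)
    lesion_radius_range: tuple[float, float] = (2.0, 6.0)
    tissue_means: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_MEANS)
    )
    noise_sd: float = 0.05
    bias_amplitude: float = 0.2
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError("target_prevalence must lie in (0, 1)")
        if self.lesion_radius_range[0] < 1.0:
            raise ValueError("lesion radii must be >= 1 voxel")
        if min(self.shape) < 4 * self.lesion_radius_range[0]:
            raise ValueError(f"shape {self.shape} too small to contain a lesion")


@dataclass(frozen=True)
class PhantomSubject:
    volume: MultiModalVolume
    mask: BinaryMask
    achieved_prevalence: float
    n_lesions: int
    seed: int


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return dist <= 1.0


def make_brain_background(
    config: PhantomConfig, rng: np.random.Generator
) -> tuple[MultiModalVolume, BinaryMask]:
    """Ellipsoidal brain of per-modality mean intensity in a zero background.

    Semi-axes are fixed fractions (0.44, 0.42, 0.40) of the grid so the brain
    fills roughly 30% of the field of view; the center jitters by up to 2% of
    the grid per axis to decorrelate subjects.
    """
    shape = config.shape
    jitter = rng.uniform(-0.02, 0.02, size=3)
    center = [(s - 1) / 2.0 + j * s for s, j in zip(shape, jitter)]
    radii = [f * s for f, s in zip((0.44, 0.42, 0.40), shape)]
    brain = _ellipsoid_mask(shape, center, radii)
    if not brain.any():
        raise ValueError(f"shape {shape} too small for a brain ellipsoid")
    channels = np.zeros((3, *shape), dtype=np.float32)
    for ci, modality in enumerate(MultiModalVolume.MODALITIES):
        channels[ci][brain] = config.tissue_means[modality][1]
    volume = MultiModalVolume(channels=channels, spacing=config.spacing)
    return volume, BinaryMask(data=brain.astype(np.uint8), spacing=config.spacing)


def place_lesions(
    brain_region: BinaryMask, config: PhantomConfig, rng: np.random.Generator
) -> BinaryMask:
    """Union of random anisotropic ellipsoids fully inside the brain.

    Lesions are added one at a time; placement stops as soon as the achieved
    prevalence (relative to the whole grid) reaches or exceeds the target, or
    when the maximum lesion count is hit.  Candidate centers are uniform over
    brain voxels; a candidate poking outside the brain is redrawn.
    """
    brain = brain_region.data.astype(bool)
    if not brain.any():
        raise ValueError("brain region is empty")
    shape = brain.shape
    total = brain.size
    brain_voxels = np.argwhere(brain)
    rmin, rmax = config.lesion_radius_range
    n_min, n_max = config.n_lesions_range
    lesions = np.zeros(shape, dtype=bool)
    n_placed = 0
    while n_placed < n_max:
        if lesions.sum() / total >= config.target_prevalence and n_placed >= n_min:
            break
        placed = False
        for _ in range(200):  # rejection budget per lesion
            center = brain_voxels[rng.integers(len(brain_voxels))]
            radii = rng.uniform(rmin, rmax, size=3)
            candidate = _ellipsoid_mask(shape, center, radii)
            if not candidate.any():
                continue
            if np.any(candidate & ~brain):
                continue
            lesions |= candidate
            n_placed += 1
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place a lesion inside the brain; radii too large for "
                f"shape {shape}"
            )
    return BinaryMask(data=lesions.astype(np.uint8), spacing=brain_region.spacing)


def sample_bias_field(
    shape: tuple[int, int, int], amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth multiplicative field from an order-3 random polynomial.

    The polynomial in normalized coordinates is scaled to max |.| = 1, mapped
    to ``1 + amplitude * poly`` and finally normalized to mean 1, so the
    max/min ratio never exceeds ``(1 + a) / (1 - a)``.
    """
    if amplitude == 0.0:
        return np.ones(shape, dtype=np.float64)
    if not 0.0 <= amplitude < 1.0:
        raise ValueError("bias amplitude must lie in [0, 1)")
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    poly = np.zeros(shape, dtype=np.float64)
    for i in range(4):
        for j in range(4 - i):
            for k in range(4 - i - j):
                if i == j == k == 0:
                    continue  # constant term is the baseline 1
                poly += rng.uniform(-1.0, 1.0) * zz**i * yy**j * xx**k
    peak = np.abs(poly).max()
    if peak > 0:
        poly /= peak
    fld = 1.0 + amplitude * poly
    return fld / fld.mean()


def render_modalities(
    background: MultiModalVolume,
    brain_region: BinaryMask,
    lesions: BinaryMask,
    config: PhantomConfig,
    rng: np.random.Generator,
) -> MultiModalVolume:
    """Paint lesion intensities, then apply bias field and Gaussian noise.

    The bias field multiplies all channels (one field per subject, as a scanner
    inhomogeneity would); noise is added only inside the brain so the zero
    background convention of skull-stripped data is preserved.
    """
    brain = brain_region.data.astype(bool)
    lesion = lesions.data.astype(bool)
    channels = background.channels.astype(np.float64).copy()
    for ci, modality in enumerate(MultiModalVolume.MODALITIES):
        channels[ci][lesion] = config.tissue_means[modality][2]
    fld = sample_bias_field(background.shape, config.bias_amplitude, rng)
    channels *= fld[None]
    if config.noise_sd > 0:
        noise = rng.normal(0.0, config.noise_sd, size=channels.shape)
        noise[:, ~brain] = 0.0
        channels += noise
    return MultiModalVolume(channels=channels.astype(np.float32), spacing=background.spacing)


def generate_subject(config: PhantomConfig) -> PhantomSubject:
    """Generate one phantom subject, bit-reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    background, brain = make_brain_background(config, rng)
    lesions = place_lesions(brain, config, rng)
    volume = render_modalities(background, brain, lesions, config, rng)
    from scipy import ndimage as _ndi

    _, n_lesions = _ndi.label(lesions.data)
    return PhantomSubject(
        volume=volume,
        mask=lesions,
        achieved_prevalence=float(lesions.data.sum()) / lesions.data.size,
        n_lesions=int(n_lesions),
        seed=config.seed,
    )


def generate_cohort(
    n: int, config: PhantomConfig, out_dir: str | Path
) -> list[SubjectRecord]:
    """Write an ``n``-subject cohort in the subject-directory layout.

    Subject ``i`` uses seed ``config.seed + i``.  The three modality masks are
    identical copies of the consensus mask, matching the six-file layout that
    :func:`lesionseg.io.validate_subject` expects.  A manifest table
    (subject_id, achieved_prevalence, n_lesions, seed) is written alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records: list[SubjectRecord] = []
    manifest_rows = []
    for i in range(n):
        sub_cfg = replace(config, seed=config.seed + i)
        subject = generate_subject(sub_cfg)
        sub_id = f"sub-{i:03d}"
        sub_dir = out_dir / sub_id
        for ci, modality in enumerate(("T1", "T2", "FLAIR")):
            write_nifti(
                VolumeGrid(subject.volume.channels[ci], subject.volume.spacing),
                sub_dir / f"{modality}.nii.gz",
            )
            write_nifti(
                VolumeGrid(
                    subject.mask.data.astype(np.float32), subject.mask.spacing
                ),
                sub_dir / f"{modality}_mask.nii.gz",
            )
        records.append(validate_subject(sub_dir))
        manifest_rows.append(
            {
                "subject_id": sub_id,
                "achieved_prevalence": subject.achieved_prevalence,
                "n_lesions": subject.n_lesions,
                "seed": sub_cfg.seed,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.csv", index=False)
    return records
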