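"""Lesion-aware balanced patch sampling and training-time augmentation.

Training patches are cubes cut jointly from the stacked modalities and the
lesion mask.  To counter the extreme foreground sparsity (<1% of voxels), a
Bernoulli coin decides per draw whether the patch is centered on a uniformly
chosen lesion voxel or on a uniformly chosen background voxel; centers near
the border are clamped so every draw yields a full patch.

The augmentation chain (training streams only) applies, in order: per-axis
random flips, one random affine (single-axis rotation, isotropic scale,
integer-free translation), additive Gaussian noise and a multiplicative bias
field.  Geometric transforms act identically on all image channels and the
mask (linear vs nearest interpolation); intensity degradations touch the image
only, so the mask stays bit-identical through them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import ndimage

from .io import BinaryMask, MultiModalVolume
from .phantom import sample_bias_field

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SamplerConfig:
    patch_size: int = 64
    p_lesion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_lesion <= 1.0:
            raise ValueError("p_lesion must lie in [0, 1]")
        if self.patch_size < 8:
            raise ValueError("patch_size must be >= 8")


@dataclass(frozen=True)
class AugmentConfig:
    flip_prob: float = 0.5
    scale_range: float = 0.10       # isotropic scale in 1 +- scale_range
    rot_range_deg: float = 10.0     # rotation about one random array axis
    translate_range: float = 5.0    # voxels per axis
    noise_sd: float = 0.03          # normalized-intensity units
    bias_amplitude: float = 0.2
    enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("flip_prob", "scale_range", "rot_range_deg", "translate_range",
                     "noise_sd", "bias_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        """Validation/test-stream configuration: no augmentation at all."""
        return cls(flip_prob=0.0, scale_range=0.0, rot_range_deg=0.0,
                   translate_range=0.0, noise_sd=0.0, bias_amplitude=0.0,
                   enabled=False)


@dataclass(frozen=True)
class Patch:
    """A paired image/mask crop; the training unit."""

    image: np.ndarray            # [3, s, s, s]
    mask: np.ndarray             # [s, s, s] in {0, 1}
    origin: tuple[int, int, int]  # voxel index of the crop's low corner
    lesion_centered: bool

    def __post_init__(self) -> None:
        if self.image.ndim != 4 or self.image.shape[0] != 3:
            raise ValueError(f"image must be [3, s, s, s], got {self.image.shape}")
        if self.mask.shape != self.image.shape[1:]:
            raise ValueError("mask shape must match image spatial shape")


def sample_center(
    mask: BinaryMask,
    lesion_centered: bool,
    patch_size: int,
    rng: np.random.Generator,
) -> tuple[int, int, int]:
    """Draw a patch center, then clamp it so the patch window fits.

    Lesion-centered draws pick uniformly among lesion voxels (falling back to
    a random center, with a warning, when the mask is empty); otherwise a
    uniformly chosen non-lesion voxel.  Clamping — rather than rejection —
    guarantees a full patch near boundaries at the cost of the chosen voxel
    not being exactly central.
    """
    data = mask.data
    if lesion_centered:
        support = np.argwhere(data > 0)
        if len(support) == 0:
            logger.warning("lesion-centered draw on an all-zero mask; random fallback")
            support = None
    else:
        support = np.argwhere(data == 0)
        if len(support) == 0:
            support = None
    if support is None:
        center = np.array([rng.integers(s) for s in data.shape])
    else:
        center = support[rng.integers(len(support))]
    half = patch_size // 2
    clamped = []
    for c, s in zip(center, data.shape):
        start = int(np.clip(c - half, 0, max(0, s - patch_size)))
        clamped.append(start + min(half, s - 1 - start))
    return tuple(int(c) for c in clamped)


def extract_patch(
    volume: MultiModalVolume,
    mask: BinaryMask,
    center: tuple[int, int, int],
    patch_size: int,
    lesion_centered: bool = False,
) -> Patch:
    """Cut the half-open window ``[c - s//2, c - s//2 + s)`` at each axis.

    Volumes smaller than the patch are zero-padded at the high end.
    """
    half = patch_size // 2
    shape = volume.shape
    starts = [int(np.clip(c - half, 0, max(0, s - patch_size))) for c, s in zip(center, shape)]
    stops = [min(st + patch_size, s) for st, s in zip(starts, shape)]
    sl = tuple(slice(st, sp) for st, sp in zip(starts, stops))
    img = volume.channels[(slice(None),) + sl]
    msk = mask.data[sl]
    pad = [(0, patch_size - (sp - st)) for st, sp in zip(starts, stops)]
    if any(p[1] > 0 for p in pad):
        img = np.pad(img, [(0, 0)] + pad)
        msk = np.pad(msk, pad)
    return Patch(
        image=np.ascontiguousarray(img, dtype=np.float32),
        mask=np.ascontiguousarray(msk, dtype=np.uint8),
        origin=tuple(starts),
        lesion_centered=lesion_centered,
    )


def _rotation_matrix(axis: int, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    other = [i for i in range(3) if i != axis]
    mat = np.eye(3)
    mat[other[0], other[0]] = c
    mat[other[0], other[1]] = -s
    mat[other[1], other[0]] = s
    mat[other[1], other[1]] = c
    return mat


def apply_augmentations(
    patch: Patch, config: AugmentConfig, rng: np.random.Generator
) -> Patch:
    """One sampled augmentation chain: flips, affine, noise, bias field.

    With all probabilities and ranges at zero the output is bit-identical to
    the input.  The mask goes through flips and the nearest-interpolated
    affine only, so it stays binary throughout.
    """
    if not config.enabled:
        return patch
    image = patch.image
    mask = patch.mask
    # per-axis flips (axial=D, coronal=H, sagittal=W after RAS canonicalization)
    if config.flip_prob > 0:
        for axis in range(3):
            if rng.random() < config.flip_prob:
                image = np.flip(image, axis=axis + 1)
                mask = np.flip(mask, axis=axis)
    # one affine: isotropic scale, single-axis rotation, translation
    if config.scale_range > 0 or config.rot_range_deg > 0 or config.translate_range > 0:
        scale = 1.0 + rng.uniform(-config.scale_range, config.scale_range)
        angle = np.deg2rad(rng.uniform(-config.rot_range_deg, config.rot_range_deg))
        axis = int(rng.integers(3))
        translation = rng.uniform(-config.translate_range, config.translate_range, size=3)
        center = (np.array(mask.shape) - 1) / 2.0
        # output -> input mapping: x_in = R(-a)/s (x_out - c - t) + c
        inv = _rotation_matrix(axis, -angle) / scale
        offset = center - inv @ (center + translation)
        image = np.stack(
            [
                ndimage.affine_transform(ch, inv, offset=offset, order=1, cval=0.0)
                for ch in image
            ]
        )
        mask = ndimage.affine_transform(
            mask.astype(np.float32), inv, offset=offset, order=0, cval=0.0
        ).astype(np.uint8)
    # image-only degradations: mask untouched
    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)
    if config.bias_amplitude > 0:
        fld = sample_bias_field(mask.shape, config.bias_amplitude, rng)
        image = image * fld[None]
    return Patch(
        image=np.ascontiguousarray(image, dtype=np.float32),
        mask=np.ascontiguousarray(mask, dtype=np.uint8),
        origin=patch.origin,
        lesion_centered=patch.lesion_centered,
    )


def balanced_patch_stream(
    volume: MultiModalVolume,
    mask: BinaryMask,
    sampler_config: SamplerConfig,
    augment_config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[Patch]:
    """Endless stream of balanced patches from one subject.

    Each draw flips a Bernoulli(``p_lesion``) coin to choose the
    lesion-centered branch; the ``lesion_centered`` flag on the yielded patch
    records the branch taken.  Reproducible given the sampler seed.
    """
    if rng is None:
        rng = np.random.default_rng(sampler_config.seed)
    if augment_config is None:
        augment_config = AugmentConfig.disabled()
    while True:
        lesion_branch = bool(rng.random() < sampler_config.p_lesion)
        center = sample_center(mask, lesion_branch, sampler_config.patch_size, rng)
        patch = extract_patch(
            volume, mask, center, sampler_config.patch_size, lesion_centered=lesion_branch
        )
        if augment_config.enabled:
            patch = apply_augmentations(patch, augment_config, rng)
        yield patch


def multi_subject_stream(
    subjects: list[tuple[MultiModalVolume, BinaryMask]],
    sampler_config: SamplerConfig,
    augment_config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> Iterator[Patch]:
    """Balanced stream drawing the source subject uniformly per patch."""
    if rng is None:
        rng = np.random.default_rng(sampler_config.seed)
    if augment_config is None:
        augment_config = AugmentConfig.disabled()
    if not subjects:
        raise ValueError("need at least one subject")
    while True:
        volume, mask = subjects[rng.integers(len(subjects))]
        lesion_branch = bool(rng.random() < sampler_config.p_lesion)
        center = sample_center(mask, lesion_branch, sampler_config.patch_size, rng)
        patch = extract_patch(
            volume, mask, center, sampler_config.patch_size, lesion_centered=lesion_branch
        )
        if augment_config.enabled:
            patch = apply_augmentations(patch, augment_config, rng)
        yield patch
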