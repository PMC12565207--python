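"""Small-blob suppression, MC-dropout / ensemble uncertainty, calibration.

Binary predictions are cleaned by deleting connected components smaller than
a voxel-count threshold (26-connectivity by default).  Predictive uncertainty
comes either from Monte-Carlo dropout — dropout kept active at inference, 30
stochastic sliding-window passes, binary entropy of the mean probability — or
from a deep ensemble, whose voxel-wise population variance is the uncertainty.
Calibration is summarized by the Expected Calibration Error over 10
equal-width confidence bins plus the point-biserial correlation between
uncertainty and the voxel-wise misclassification indicator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .io import BinaryMask, MultiModalVolume
from .networks import _SegmentationModel, sliding_window_predict
from .nn.layers import Mode, SpatialDropout3d, walk_layers


@dataclass(frozen=True)
class UncertaintyMap:
    mean_prob: np.ndarray
    uncertainty: np.ndarray
    method: str               # "mc_dropout" or "ensemble"
    n_samples: int

    def __post_init__(self) -> None:
        if self.mean_prob.shape != self.uncertainty.shape:
            raise ValueError("mean_prob and uncertainty shapes differ")
        if np.any(self.uncertainty < -1e-12):
            raise ValueError("uncertainty must be non-negative")


@dataclass(frozen=True)
class CalibrationReport:
    ece: float
    bin_edges: np.ndarray
    bin_confidence: np.ndarray
    bin_accuracy: np.ndarray
    bin_counts: np.ndarray
    unc_error_correlation: float


def remove_small_blobs(mask: BinaryMask, min_voxels: int, connectivity: int = 26) -> BinaryMask:
    """Drop connected components with fewer than ``min_voxels`` voxels.

    ``connectivity`` is 6 (faces), 18 (faces+edges) or 26 (full neighbourhood).
    The output is always a subset of the input; ``min_voxels=0`` is the identity.
    """
    if min_voxels < 0:
        raise ValueError("min_voxels must be >= 0")
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError(f"connectivity must be one of {sorted(rank)}")
    data = mask.data.astype(bool)
    if min_voxels <= 1 or not data.any():
        return BinaryMask(data=data.astype(np.uint8), spacing=mask.spacing)
    structure = ndimage.generate_binary_structure(3, rank[connectivity])
    labels, n = ndimage.label(data, structure=structure)
    if n == 0:
        return BinaryMask(data=data.astype(np.uint8), spacing=mask.spacing)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return BinaryMask(data=keep[labels].astype(np.uint8), spacing=mask.spacing)


def binary_entropy(p: np.ndarray | float) -> np.ndarray | float:
    """Entropy of a Bernoulli(p) in nats, with the 0*log(0) = 0 convention."""
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    q = p[interior]
    out[interior] = -(q * np.log(q) + (1 - q) * np.log(1 - q))
    return out if out.ndim else float(out)


def mc_dropout_predict(
    network: _SegmentationModel,
    volume: MultiModalVolume,
    n_passes: int = 30,
    seed: int = 0,
    patch_size: int = 64,
    overlap: float = 0.5,
) -> UncertaintyMap:
    """MC-dropout inference: dropout active, mean over stochastic passes.

    Uncertainty is the binary predictive entropy of the MC mean probability.
    Requires the network to contain dropout layers with a non-zero rate —
    otherwise every pass is identical and MC dropout is meaningless.
    """
    if n_passes < 2:
        raise ValueError("n_passes must be >= 2")
    has_dropout = any(
        isinstance(l, SpatialDropout3d) and l.p > 0 for l in walk_layers(network)
    )
    if not has_dropout:
        raise ValueError("network has no active dropout layers; MC dropout undefined")
    rng = np.random.default_rng(seed)
    acc = None
    for _ in range(n_passes):
        mode = Mode(training=False, mc_dropout=True, rng=rng)
        pred = sliding_window_predict(network, volume, patch_size=patch_size,
                                      overlap=overlap, mode=mode)
        acc = pred.probs if acc is None else acc + pred.probs
    mean = acc / n_passes
    return UncertaintyMap(mean_prob=mean, uncertainty=binary_entropy(mean),
                          method="mc_dropout", n_samples=n_passes)


def ensemble_predict(
    members: Sequence[_SegmentationModel],
    volume: MultiModalVolume,
    patch_size: int = 64,
    overlap: float = 0.5,
) -> UncertaintyMap:
    """Deep-ensemble inference: member mean and population variance per voxel."""
    if len(members) < 2:
        raise ValueError("an ensemble needs at least 2 members")
    specs = {m.spec.to_dict().__repr__() for m in members}
    if len(specs) != 1:
        raise ValueError("ensemble members have mismatched network specs")
    fields = np.stack([
        sliding_window_predict(m, volume, patch_size=patch_size, overlap=overlap).probs
        for m in members
    ])
    return UncertaintyMap(
        mean_prob=fields.mean(axis=0),
        uncertainty=fields.var(axis=0),  # population variance, <= 0.25
        method="ensemble",
        n_samples=len(members),
    )


def expected_calibration_error(
    probs: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
    uncertainty: np.ndarray | None = None,
) -> CalibrationReport:
    """Binned ECE over max-probability confidence, plus uncertainty-error correlation.

    Confidence is ``max(p, 1-p)`` of the voxel probability; bins are equal
    width over [0.5, 1].  ECE is the count-weighted mean absolute gap between
    per-bin confidence and per-bin accuracy of the thresholded prediction.
    The correlation is the Pearson (point-biserial) coefficient between the
    uncertainty field (binary entropy of the probability unless given) and
    the misclassification indicator.
    """
    probs = np.asarray(probs, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must align")
    pred = probs > 0.5
    correct = pred == labels.astype(bool)
    confidence = np.maximum(probs, 1.0 - probs)
    edges = np.linspace(0.5, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(confidence, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    conf_sum = np.bincount(idx, weights=confidence, minlength=n_bins)
    acc_sum = np.bincount(idx, weights=correct.astype(np.float64), minlength=n_bins)
    with np.errstate(invalid="ignore"):
        bin_conf = np.where(counts > 0, conf_sum / np.maximum(counts, 1), 0.0)
        bin_acc = np.where(counts > 0, acc_sum / np.maximum(counts, 1), 0.0)
    ece = float(np.sum(counts / probs.size * np.abs(bin_acc - bin_conf)))
    unc = binary_entropy(probs) if uncertainty is None else np.asarray(uncertainty).ravel()
    errors = (~correct).astype(np.float64)
    if np.ptp(unc) == 0 or np.ptp(errors) == 0:
        corr = 0.0  # degenerate: no variation to correlate
    else:
        corr = float(stats.pearsonr(unc, errors)[0])
    return CalibrationReport(
        ece=ece, bin_edges=edges, bin_confidence=bin_conf,
        bin_accuracy=bin_acc, bin_counts=counts, unc_error_correlation=corr,
    )


def uncertainty_error_summary(
    unc_map: UncertaintyMap, target: BinaryMask, threshold: float = 0.5
) -> dict[str, float]:
    """Mean uncertainty over misclassified vs correctly classified voxels."""
    pred = unc_map.mean_prob > threshold
    errors = pred != target.data.astype(bool)
    unc = unc_map.uncertainty
    return {
        "mean_uncertainty_errors": float(unc[errors].mean()) if errors.any() else 0.0,
        "mean_uncertainty_correct": float(unc[~errors].mean()) if (~errors).any() else 0.0,
        "error_fraction": float(errors.mean()),
    }


def overlay_slice_png(
    volume: MultiModalVolume,
    prediction: np.ndarray,
    uncertainty: np.ndarray | None,
    path,
    axial_index: int | None = None,
    channel: int = 2,
) -> None:
    """Export one axial slice with prediction (and uncertainty) overlays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = axial_index if axial_index is not None else volume.shape[0] // 2
    n_panels = 3 if uncertainty is not None else 2
    fig, axes = plt.subplots(1, n_panels, figsize=(4 * n_panels, 4))
    axes[0].imshow(volume.channels[channel, k], cmap="gray")
    axes[0].set_title("FLAIR")
    axes[1].imshow(volume.channels[channel, k], cmap="gray")
    axes[1].imshow(np.ma.masked_where(prediction[k] == 0, prediction[k]),
                   cmap="autumn", alpha=0.6)
    axes[1].set_title("prediction")
    if uncertainty is not None:
        im = axes[2].imshow(uncertainty[k], cmap="inferno")
        fig.colorbar(im, ax=axes[2], shrink=0.8)
        axes[2].set_title("uncertainty")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
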