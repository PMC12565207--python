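"""Composite Dice+BCE training loss and voxel-level evaluation metrics.

The training objective is the convex combination

    L = alpha * L_Dice + (1 - alpha) * L_BCE,        alpha = 0.7 by default,

with the soft Dice loss in its squared-denominator form

    L_Dice = 1 - (2 * sum(p*y) + eps) / (sum(p^2) + sum(y^2) + eps)

and BCE as the negative mean log-likelihood, probabilities clipped to
``[delta, 1 - delta]`` before the logarithms.  Evaluation metrics (Dice,
precision, recall, accuracy, specificity) derive from voxel-wise confusion
counts; 0/0 ratios are reported as 0 with an ``undefined`` flag so cohort
aggregation stays total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLIP_DELTA = 1e-7


@dataclass(frozen=True)
class LossConfig:
    alpha: float = 0.7
    eps: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.eps <= 0:
            raise ValueError("eps must be positive")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    dice: float
    precision: float
    recall: float
    accuracy: float
    specificity: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "dice": self.dice, "precision": self.precision, "recall": self.recall,
            "accuracy": self.accuracy, "specificity": self.specificity,
        }


def _check_shapes(pred: np.ndarray, target: np.ndarray) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")


def dice_loss(pred: np.ndarray, target: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss with squared-denominator smoothing; 0 on empty-empty."""
    _check_shapes(pred, target)
    p = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    num = 2.0 * float((p * y).sum()) + eps
    den = float((p * p).sum()) + float((y * y).sum()) + eps
    return 1.0 - num / den


def bce_loss(pred: np.ndarray, target: np.ndarray, delta: float = CLIP_DELTA) -> float:
    """Negative mean voxel-wise log-likelihood, probabilities clipped to [delta, 1-delta]."""
    _check_shapes(pred, target)
    p = np.clip(np.asarray(pred, dtype=np.float64), delta, 1.0 - delta)
    y = np.asarray(target, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def composite_loss(pred: np.ndarray, target: np.ndarray,
                   config: LossConfig = LossConfig()) -> float:
    """``alpha * Dice + (1 - alpha) * BCE``."""
    return (config.alpha * dice_loss(pred, target, config.eps)
            + (1.0 - config.alpha) * bce_loss(pred, target))


def composite_loss_grad(
    pred: np.ndarray, target: np.ndarray, config: LossConfig = LossConfig()
) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to the probabilities."""
    _check_shapes(pred, target)
    p = np.asarray(pred, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64)
    eps = config.eps
    num = 2.0 * (p * y).sum() + eps
    den = (p * p).sum() + (y * y).sum() + eps
    l_dice = 1.0 - num / den
    g_dice = (num * 2.0 * p - 2.0 * y * den) / den**2
    pc = np.clip(p, CLIP_DELTA, 1.0 - CLIP_DELTA)
    l_bce = float(-np.mean(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))
    g_bce = (-y / pc + (1.0 - y) / (1.0 - pc)) / p.size
    loss = config.alpha * l_dice + (1.0 - config.alpha) * l_bce
    grad = config.alpha * g_dice + (1.0 - config.alpha) * g_bce
    return float(loss), grad


def confusion_counts(pred_binary: np.ndarray, target: np.ndarray) -> ConfusionCounts:
    """Voxel-wise confusion matrix of two binary fields of equal shape."""
    _check_shapes(pred_binary, target)
    p = np.asarray(pred_binary)
    y = np.asarray(target)
    for name, arr in (("pred", p), ("target", y)):
        if not np.all(np.isin(np.unique(arr), (0, 1))):
            raise ValueError(f"{name} must be binary")
    p = p.astype(bool)
    y = y.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & y)),
        fp=int(np.count_nonzero(p & ~y)),
        tn=int(np.count_nonzero(~p & ~y)),
        fn=int(np.count_nonzero(~p & y)),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metric_report(counts: ConfusionCounts) -> MetricReport:
    """Dice, precision, recall, accuracy and specificity from confusion counts."""
    undefined: list[str] = []
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    return MetricReport(
        dice=_ratio(2 * tp, 2 * tp + fp + fn, "dice", undefined),
        precision=_ratio(tp, tp + fp, "precision", undefined),
        recall=_ratio(tp, tp + fn, "recall", undefined),
        accuracy=_ratio(tp + tn, counts.total, "accuracy", undefined),
        specificity=_ratio(tn, tn + fp, "specificity", undefined),
        undefined=tuple(undefined),
    )


def evaluate_masks(pred_binary: np.ndarray, target: np.ndarray) -> MetricReport:
    return metric_report(confusion_counts(pred_binary, target))


def dice_score(pred_binary: np.ndarray, target: np.ndarray) -> float:
    return metric_report(confusion_counts(pred_binary, target)).dice


def cohort_metric_table(
    reports: dict[str, MetricReport], pooled: MetricReport | None = None
) -> pd.DataFrame:
    """Flat subject_id x metric table, optionally with a pooled summary row.

    Pooled (voxels merged across subjects before computing ratios) is the
    default cohort summary; per-subject means can be read off the table.
    """
    rows = [{"subject_id": sid, **rep.as_dict()} for sid, rep in reports.items()]
    if pooled is not None:
        rows.append({"subject_id": "POOLED", **pooled.as_dict()})
    return pd.DataFrame(rows)
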