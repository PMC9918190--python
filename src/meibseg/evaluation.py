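"""Pixel-wise segmentation evaluation.

Predicted masks are compared with expert (or synthetic ground-truth) masks
pixel by pixel: the labeled region is the positive class.  Reported metrics
are sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy
(TP+TN)/total, and the Dice index 2TP/(2TP+FP+FN).  ROC curves sweep the
binarization threshold over the predicted probability maps, pooling pixels
across the evaluated images (a per-image macro average is available as a
secondary reduction), and the AUC is the trapezoidal area under (FPR, TPR).

The gland-area-to-tarsus-area ratio quantifies meibomian gland loss: a
healthy lid has glands covering a substantial fraction of the tarsal plate,
and atrophy lowers the ratio.

Metrics with an empty denominator (e.g. sensitivity with no positive ground
truth) are reported as NaN - an explicit "undefined" marker - never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ROCResult",
    "confusion",
    "metrics",
    "roc_curve",
    "macro_average_auc",
    "gland_area_ratio",
]

UNDEFINED = float("nan")


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


@dataclass(frozen=True)
class MetricsReport:
    sensitivity: float
    specificity: float
    accuracy: float
    dice: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "dice": self.dice,
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "tn": self.counts.tn, "fn": self.counts.fn},
        }


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray  # descending, within [0, 1]
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.dtype == bool:
        return a
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1 or bool)")
    return a.astype(bool)


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Per-pixel confusion counts; the labeled (ground-truth) area is positive."""
    pred = _check_binary(pred_mask, "pred_mask")
    gt = _check_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & gt)),
        fp=int(np.sum(pred & ~gt)),
        tn=int(np.sum(~pred & ~gt)),
        fn=int(np.sum(~pred & gt)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else UNDEFINED


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, accuracy and Dice from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")
    return MetricsReport(
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.tn + counts.fp),
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        dice=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn),
        counts=counts,
    )


def _pool(prob_maps: Sequence[np.ndarray], gt_masks: Sequence[np.ndarray]):
    if len(prob_maps) == 0 or len(prob_maps) != len(gt_masks):
        raise ValueError("need equally many (>=1) probability maps and ground-truth masks")
    probs, gts = [], []
    for p, g in zip(prob_maps, gt_masks):
        p = np.asarray(p, dtype=np.float64)
        g = _check_binary(g, "gt_mask")
        if p.shape != g.shape:
            raise ValueError(f"shape mismatch: probs {p.shape} vs gt {g.shape}")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        probs.append(p.ravel())
        gts.append(g.ravel())
    return np.concatenate(probs), np.concatenate(gts)


def _roc_from_pool(scores: np.ndarray, labels: np.ndarray,
                   n_thresholds: int | None) -> ROCResult:
    P = int(labels.sum())
    N = int(labels.size - P)
    if P == 0 or N == 0:
        raise ValueError("ROC undefined: ground truth is single-class")
    if n_thresholds is None:
        # staircase at every distinct score: trapezoidal AUC then equals the
        # Mann-Whitney pair-counting statistic
        uniq = np.unique(scores)[::-1]
        thresholds = np.concatenate(([1.0], uniq, [0.0]))
        thresholds = np.unique(thresholds)[::-1]
    else:
        if n_thresholds < 2:
            raise ValueError("n_thresholds must be >= 2")
        thresholds = np.linspace(1.0, 0.0, n_thresholds)
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    order = np.argsort(scores, kind="stable")
    sorted_scores = scores[order]
    pos_cum = np.cumsum(labels[order][::-1])[::-1]  # positives with score >= rank
    neg_cum = np.cumsum((~labels.astype(bool))[order][::-1])[::-1]
    for i, t in enumerate(thresholds):
        if t <= 0.0:
            # threshold 0 declares every pixel positive, pinning the curve at (1,1)
            tp, fp = P, N
        else:
            idx = np.searchsorted(sorted_scores, t, side="right")
            tp = int(pos_cum[idx]) if idx < scores.size else 0
            fp = int(neg_cum[idx]) if idx < scores.size else 0
        tpr[i] = tp / P
        fpr[i] = fp / N
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def roc_curve(
    prob_maps: Sequence[np.ndarray],
    gt_masks: Sequence[np.ndarray],
    n_thresholds: int | None = 101,
) -> ROCResult:
    """Pooled pixel-wise ROC over a collection of images.

    Pixels from every image are pooled into one population, the positive
    predicate is score > threshold (all-positive at threshold 0), and the
    AUC is the trapezoidal area.  ``n_thresholds=None`` places a threshold
    at every distinct score, recovering the exact ROC staircase.
    """
    scores, labels = _pool(prob_maps, gt_masks)
    return _roc_from_pool(scores, labels, n_thresholds)


def macro_average_auc(
    prob_maps: Sequence[np.ndarray],
    gt_masks: Sequence[np.ndarray],
    n_thresholds: int | None = 101,
) -> float:
    """Secondary reduction: mean of per-image AUCs (images weigh equally)."""
    aucs = [
        roc_curve([p], [g], n_thresholds=n_thresholds).auc
        for p, g in zip(prob_maps, gt_masks)
    ]
    return float(np.mean(aucs))


def gland_area_ratio(gland_mask: np.ndarray, tarsus_mask: np.ndarray) -> float:
    """|gland ∩ tarsus| / |tarsus|: the gland coverage of the tarsal plate.

    Its complement is the meibomian gland loss proportion.  A gland mask
    extending beyond the tarsus is clipped with a warning.
    """
    gland = _check_binary(gland_mask, "gland_mask")
    tarsus = _check_binary(tarsus_mask, "tarsus_mask")
    if gland.shape != tarsus.shape:
        raise ValueError(f"shape mismatch: gland {gland.shape} vs tarsus {tarsus.shape}")
    if not tarsus.any():
        raise ValueError("tarsus mask is empty; gland area ratio undefined")
    outside = int(np.sum(gland & ~tarsus))
    if outside:
        warnings.warn(f"{outside} gland pixels outside the tarsus were clipped")
    return float(np.sum(gland & tarsus) / np.sum(tarsus))
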