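"""Per-class Dice evaluation, percentile summaries and confusion matrices.

The headline metric is the per-class Sørensen–Dice coefficient
``DSC_c = 2|X_c ∩ Y_c| / (|X_c| + |Y_c|)`` between predicted and true voxel
sets.  A model run is summarized as ``median_{-(median-p16)}^{+(p84-median)}``
over the classes with at least one true-positive voxel (the 16/84
percentiles bracket roughly one sigma), together with the fraction of
ground-truth classes that were detected at all (DSC_c > 0) in brackets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .volumes import LabelVolume

__all__ = [
    "ClassScores",
    "SummaryStats",
    "dsc_per_class",
    "summarize",
    "confusion_matrix",
    "confusion_report",
]


@dataclass
class ClassScores:
    """Per-foreground-class Dice results (index 0 of each array = class 1)."""

    dsc: np.ndarray                 # DSC_c, 0 where no true positive
    has_true_positive: np.ndarray   # bool
    present_in_gt: np.ndarray       # bool
    n_classes: int                  # N including background

    def __post_init__(self):
        if not np.array_equal(self.dsc > 0, self.has_true_positive):
            raise ValueError("DSC_c > 0 must coincide with having a true positive")


@dataclass
class SummaryStats:
    median: float
    p16: float
    p84: float
    detected_fraction: float

    def __post_init__(self):
        if not (self.p16 <= self.median <= self.p84):
            raise ValueError("percentiles out of order")
        if not 0.0 <= self.detected_fraction <= 1.0:
            raise ValueError("detected_fraction outside [0, 1]")

    def format(self, digits: int = 2) -> str:
        """``median_{-σ}^{+σ}, (fraction)`` in the conventional table notation."""
        lo = self.median - self.p16
        hi = self.p84 - self.median
        return (
            f"{self.median:.{digits}f}_{{-{lo:.{digits}f}}}^{{+{hi:.{digits}f}}}, "
            f"({self.detected_fraction:.2f})"
        )


def _check_shapes(pred: LabelVolume, gt: LabelVolume):
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")


def dsc_per_class(pred: LabelVolume, gt: LabelVolume) -> ClassScores:
    """Sørensen–Dice coefficient for every foreground class.

    Classes absent from both volumes are flagged not-present (their DSC slot
    is 0 and they are excluded from summaries); the background class is
    never scored.
    """
    _check_shapes(pred, gt)
    n = max(pred.n_classes, gt.n_classes)
    cm = confusion_matrix(pred, gt, normalize=False, n_classes=n)
    inter = np.diag(cm)[1:]
    pred_sz = cm.sum(axis=0)[1:]
    gt_sz = cm.sum(axis=1)[1:]
    denom = pred_sz + gt_sz
    with np.errstate(invalid="ignore", divide="ignore"):
        dsc = np.where(denom > 0, 2.0 * inter / np.maximum(denom, 1), 0.0)
    return ClassScores(
        dsc=dsc,
        has_true_positive=inter > 0,
        present_in_gt=gt_sz > 0,
        n_classes=n,
    )


def summarize(scores: ClassScores) -> SummaryStats:
    """Median and 16/84 percentiles over true-positive classes.

    Percentiles use linear interpolation between order statistics.  The
    detected fraction counts classes with DSC_c > 0 among classes present in
    the ground truth.
    """
    n_present = int(scores.present_in_gt.sum())
    if n_present == 0:
        raise ValueError("no classes present in ground truth")
    tp = scores.dsc[scores.has_true_positive]
    if tp.size == 0:
        raise ValueError("no class has a true-positive voxel; summary undefined")
    p16, med, p84 = np.percentile(tp, [16, 50, 84], method="linear")
    detected = int((scores.has_true_positive & scores.present_in_gt).sum())
    return SummaryStats(
        median=float(med),
        p16=float(p16),
        p84=float(p84),
        detected_fraction=detected / n_present,
    )


def confusion_matrix(
    pred: LabelVolume,
    gt: LabelVolume,
    normalize: bool = False,
    n_classes: int | None = None,
) -> np.ndarray:
    """N x N voxel count matrix with ground-truth classes as rows.

    Entry (i, j) counts voxels with true class i predicted as class j.  With
    ``normalize`` every nonempty row is divided by its sum, giving per-class
    recall profiles; rows of absent classes stay all-zero.
    """
    _check_shapes(pred, gt)
    n = n_classes or max(pred.n_classes, gt.n_classes)
    idx = gt.labels.astype(np.int64).ravel() * n + pred.labels.astype(np.int64).ravel()
    cm = np.bincount(idx, minlength=n * n).reshape(n, n).astype(np.float64)
    if normalize:
        row = cm.sum(axis=1, keepdims=True)
        cm = np.divide(cm, row, out=np.zeros_like(cm), where=row > 0)
    return cm


def confusion_report(matrix: np.ndarray, top_k: int = 20) -> List[Tuple[int, int, float]]:
    """Largest off-diagonal confusion rates, descending.

    Supports picking confusion sets from the most frequent confusions
    observed on a validation set.
    """
    m = np.asarray(matrix, dtype=float).copy()
    np.fill_diagonal(m, 0.0)
    gt_idx, pr_idx = np.nonzero(m > 0)
    rates = m[gt_idx, pr_idx]
    order = np.argsort(-rates, kind="stable")[:top_k]
    return [(int(gt_idx[i]), int(pr_idx[i]), float(rates[i])) for i in order]
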