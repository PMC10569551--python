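"""Confusion-matrix accounting and segmentation metrics.

Predictions are compared with the ground truth voxelwise inside an
evaluation mask (the brain mask), yielding TP/TN/FP/FN counts, from which
accuracy, recall, precision and the Dice coefficient (DSC) are derived.
Row-normalised confusion matrices and unweighted cross-stack averages
mirror the standard reporting format for this kind of study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "confusion_counts",
    "compute_metrics",
    "confusion_rows",
    "aggregate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """Accuracy, recall, precision and Dice coefficient, as fractions in [0, 1]."""

    accuracy: float
    recall: float
    precision: float
    dsc: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "dsc": self.dsc,
        }


def confusion_counts(
    pred: np.ndarray, gt: np.ndarray, eval_mask: np.ndarray | None = None
) -> ConfusionCounts:
    """Count TP/TN/FP/FN over voxels where *eval_mask* is set.

    With no mask, every voxel is evaluated.
    """
    pred = np.asarray(pred) != 0
    gt = np.asarray(gt) != 0
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    if eval_mask is not None:
        eval_mask = np.asarray(eval_mask) != 0
        if eval_mask.shape != pred.shape:
            raise ValueError("eval_mask shape mismatch")
        pred = pred[eval_mask]
        gt = gt[eval_mask]
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Derive the four metrics; ratios with empty denominators are 0."""
    if counts.total == 0:
        raise ValueError("no voxels evaluated")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    accuracy = (tp + tn) / counts.total
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    dsc = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    return Metrics(accuracy=accuracy, recall=recall, precision=precision, dsc=dsc)


def dsc_from_precision_recall(precision: float, recall: float) -> float:
    """Dice as the harmonic mean of precision and recall."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def confusion_rows(counts: ConfusionCounts) -> dict:
    """Row-normalised 2x2 confusion matrix in percent.

    Rows are conditioned on the ground truth: the BG(GT) row is
    ``(tn, fp) / (tn + fp)`` and the FG(GT) row is ``(fn, tp) / (fn + tp)``;
    each row sums to 100.  A row with an empty ground-truth class is
    reported as ``None``.
    """
    bg_total = counts.tn + counts.fp
    fg_total = counts.fn + counts.tp
    bg_row = (
        (100.0 * counts.tn / bg_total, 100.0 * counts.fp / bg_total)
        if bg_total > 0
        else None
    )
    fg_row = (
        (100.0 * counts.fn / fg_total, 100.0 * counts.tp / fg_total)
        if fg_total > 0
        else None
    )
    return {"BG(GT)": bg_row, "FG(GT)": fg_row}


def aggregate(per_stack: Sequence[Metrics]) -> Metrics:
    """Unweighted arithmetic mean of each metric across stacks."""
    if len(per_stack) == 0:
        raise ValueError("no metrics to aggregate")
    return Metrics(
        accuracy=float(np.mean([m.accuracy for m in per_stack])),
        recall=float(np.mean([m.recall for m in per_stack])),
        precision=float(np.mean([m.precision for m in per_stack])),
        dsc=float(np.mean([m.dsc for m in per_stack])),
    )
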