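"""Segmentation evaluation: per-class and macro overlap metrics, plus the
present/absent identification accounting for empty and unpredicted labels.

All per-class metrics are one-vs-rest voxel counts: for class k,
dice = 2TP/(2TP+FP+FN), iou = TP/(TP+FP+FN), accuracy = (TP+TN)/total,
precision = TP/(TP+FP), sensitivity = TP/(TP+FN); for binary counts the
F1-score coincides with Dice (algebraic identity) and is reported as such.
The macro value mEM of a metric is the unweighted mean over the N included
classes.

Empty-class conventions (configurable through :class:`EvaluationPolicy`):
classes empty in both ground truth and prediction carry no voxel evidence and
are excluded from macro averaging — they are routed to the identification
tally instead, where a ground-truth-empty class predicted empty counts as a
correct identification, predicted non-empty as a false identification, and a
ground-truth-present class predicted empty as a missing segment.  Background
(class 0) is excluded from macro metrics by default because its dominance
inflates accuracy-style metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .label_scheme import LabelScheme, default_scheme
from .volume_io import LabelVolume

__all__ = ["ClassMetrics", "MetricsReport", "IdentificationTally",
           "EvaluationPolicy", "confusion_counts", "class_metrics",
           "macro_average", "tally_identification", "evaluate_case"]

_METRIC_NAMES = ("dice", "iou", "accuracy", "precision", "sensitivity", "f1")


@dataclass(frozen=True)
class ClassMetrics:
    dice: float
    iou: float
    accuracy: float
    precision: float
    sensitivity: float
    f1: float
    gt_voxels: int
    pred_voxels: int


@dataclass(frozen=True)
class MetricsReport:
    per_class: dict[int, ClassMetrics]
    macro: dict[str, float]           # mDice, mIoU, ...
    n_classes_averaged: int

    def as_rows(self) -> list[dict]:
        rows = []
        for k, m in sorted(self.per_class.items()):
            row = {"class": k}
            row.update({name: getattr(m, name) for name in _METRIC_NAMES})
            row.update({"gt_voxels": m.gt_voxels, "pred_voxels": m.pred_voxels})
            rows.append(row)
        return rows


@dataclass(frozen=True)
class IdentificationTally:
    correct_identify: int
    false_identify: int
    missing_segment: int
    gt_empty_classes: tuple[int, ...]
    false_identify_classes: tuple[int, ...]
    missing_segment_classes: tuple[int, ...]


@dataclass(frozen=True)
class EvaluationPolicy:
    include_background: bool = False
    include_gt_empty_in_macro: bool = False   # if True, gt-empty/pred-present scores 0
    min_voxels: int = 1                       # presence threshold for the tally


def _check_grids(a: LabelVolume, b: LabelVolume) -> None:
    if a.shape != b.shape:
        raise ValueError(f"label grids differ: {a.shape} vs {b.shape}")


def _counts_per_class(pred: np.ndarray, gt: np.ndarray, n_classes: int):
    """Vectorised one-vs-rest confusion counts for classes 0..n_classes."""
    k = n_classes + 1
    joint = np.bincount(gt.ravel().astype(np.int64) * k + pred.ravel(),
                        minlength=k * k).reshape(k, k)
    gt_tot = joint.sum(axis=1)
    pred_tot = joint.sum(axis=0)
    tp = np.diag(joint).astype(np.int64)
    fn = gt_tot - tp
    fp = pred_tot - tp
    tn = joint.sum() - tp - fn - fp
    return tp, fp, fn, tn


def confusion_counts(pred: LabelVolume, gt: LabelVolume,
                     class_k: int) -> tuple[int, int, int, int]:
    """One-vs-rest voxel confusion counts (TP, FP, FN, TN) for class ``class_k``."""
    _check_grids(pred, gt)
    p = pred.labels == class_k
    g = gt.labels == class_k
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return tp, fp, fn, tn


def _safe_div(num: float, den: float, empty_value: float = 1.0) -> float:
    """0/0 follows the empty-class convention: a vacuous ratio scores
    `empty_value` (perfect agreement on absence)."""
    return float(num) / float(den) if den else float(empty_value)


def class_metrics(tp: int, fp: int, fn: int, tn: int) -> ClassMetrics:
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be nonnegative")
    total = tp + fp + fn + tn
    dice = _safe_div(2 * tp, 2 * tp + fp + fn)
    return ClassMetrics(
        dice=dice,
        iou=_safe_div(tp, tp + fp + fn),
        accuracy=_safe_div(tp + tn, total),
        precision=_safe_div(tp, tp + fp),
        sensitivity=_safe_div(tp, tp + fn),
        f1=dice,  # identical to Dice for binary voxel counts
        gt_voxels=tp + fn,
        pred_voxels=tp + fp,
    )


def macro_average(per_class_values: dict[int, float],
                  included: set[int] | None = None) -> tuple[float, int]:
    """Unweighted mean over exactly the included classes; returns (mean, N)."""
    keys = sorted(per_class_values) if included is None else sorted(included)
    if not keys:
        raise ValueError("macro average over an empty class set")
    vals = [per_class_values[k] for k in keys]
    return float(np.mean(vals)), len(keys)


def tally_identification(pred: LabelVolume, gt: LabelVolume,
                         scheme: LabelScheme | None = None,
                         min_voxels: int = 1) -> IdentificationTally:
    """Present/absent accounting over all scheme classes.

    A class is "predicted present" iff its predicted voxel count is at least
    ``min_voxels``.  Ground-truth-empty classes predicted empty are correct
    identifications; predicted non-empty, false identifications.  Ground-truth
    present classes predicted empty are missing segments.
    """
    _check_grids(pred, gt)
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    scheme = scheme or default_scheme()
    n = scheme.num_classes
    gt_counts = np.bincount(gt.labels.ravel(), minlength=n + 1)
    pred_counts = np.bincount(pred.labels.ravel(), minlength=n + 1)
    correct, false_id, missing = [], [], []
    for k in range(1, n + 1):
        gt_present = gt_counts[k] > 0
        pred_present = pred_counts[k] >= min_voxels
        if not gt_present:
            (false_id if pred_present else correct).append(k)
        elif not pred_present:
            missing.append(k)
    gt_empty = tuple(k for k in range(1, n + 1) if gt_counts[k] == 0)
    return IdentificationTally(
        correct_identify=len(correct), false_identify=len(false_id),
        missing_segment=len(missing), gt_empty_classes=gt_empty,
        false_identify_classes=tuple(false_id),
        missing_segment_classes=tuple(missing))


def evaluate_case(pred: LabelVolume, gt: LabelVolume,
                  scheme: LabelScheme | None = None,
                  policy: EvaluationPolicy = EvaluationPolicy()
                  ) -> tuple[MetricsReport, IdentificationTally]:
    """Full per-case evaluation: per-class metrics, macro averages, and the
    identification tally, under the stated empty-class policy."""
    _check_grids(pred, gt)
    scheme = scheme or default_scheme()
    n = scheme.num_classes
    tp, fp, fn, tn = _counts_per_class(pred.labels, gt.labels, n)
    tally = tally_identification(pred, gt, scheme, policy.min_voxels)

    per_class: dict[int, ClassMetrics] = {}
    included: set[int] = set()
    for k in range(0, n + 1):
        gt_present = (tp[k] + fn[k]) > 0
        pred_present = (tp[k] + fp[k]) > 0
        if k == 0:
            per_class[k] = class_metrics(tp[k], fp[k], fn[k], tn[k])
            if policy.include_background:
                included.add(k)
            continue
        if not gt_present and not pred_present:
            continue  # no voxel evidence; the tally covers it
        if not gt_present and not policy.include_gt_empty_in_macro:
            continue  # false identification; tallied, not averaged
        per_class[k] = class_metrics(tp[k], fp[k], fn[k], tn[k])
        included.add(k)

    if included:
        macro = {}
        for name in _METRIC_NAMES:
            vals = {k: getattr(per_class[k], name) for k in included}
            macro["m" + name.capitalize() if name != "iou" else "mIoU"], n_avg = \
                macro_average(vals)
    else:  # degenerate: nothing to average
        macro = {("m" + nm.capitalize() if nm != "iou" else "mIoU"): float("nan")
                 for nm in _METRIC_NAMES}
        n_avg = 0
    return MetricsReport(per_class=per_class, macro=macro,
                         n_classes_averaged=n_avg), tally
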