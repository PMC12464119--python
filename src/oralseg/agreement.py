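"""Inter-annotator consistency: per-label Dice between two raters and the
intraclass correlation coefficient (ICC) for calibration sets.

The ICC form implemented is ICC(2,1): two-way random effects, absolute
agreement, single measures — the standard choice when raters are regarded as
interchangeable.  It is computed from the two-way ANOVA mean-squares
decomposition

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

with n targets, k raters, MSR the between-target, MSC the between-rater and
MSE the residual mean square.  The measurement fed to the ICC for label maps
is the per-label volume (voxel count x voxel volume) per rater per case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .label_scheme import LabelScheme, default_scheme
from .metrics import confusion_counts, _check_grids
from .volume_io import LabelVolume

__all__ = ["RatingsTable", "ICCResult", "pairwise_label_dsc", "icc",
           "label_volumes_table"]


@dataclass(frozen=True)
class RatingsTable:
    """Targets x raters matrix of continuous measurements (no missing cells)."""

    values: np.ndarray
    target_ids: tuple = ()
    rater_ids: tuple = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("ratings must be a 2-D targets x raters matrix")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 targets and 2 raters")
        if not np.isfinite(v).all():
            raise ValueError("ratings table has missing or non-finite cells")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    form: str
    ms_rows: float      # between-target mean square (MSR)
    ms_cols: float      # between-rater mean square (MSC)
    ms_error: float     # residual mean square (MSE)
    n_targets: int
    n_raters: int


def pairwise_label_dsc(lv_a: LabelVolume, lv_b: LabelVolume,
                       scheme: LabelScheme | None = None) -> dict[int, float]:
    """Per-class Dice between two raters' label maps on the same grid;
    classes empty in both maps are skipped."""
    _check_grids(lv_a, lv_b)
    scheme = scheme or default_scheme()
    out: dict[int, float] = {}
    counts_a = np.bincount(lv_a.labels.ravel(), minlength=scheme.num_classes + 1)
    counts_b = np.bincount(lv_b.labels.ravel(), minlength=scheme.num_classes + 1)
    for k in range(1, scheme.num_classes + 1):
        if counts_a[k] == 0 and counts_b[k] == 0:
            continue
        tp, fp, fn, _ = confusion_counts(lv_a, lv_b, k)
        out[k] = 2.0 * tp / (2.0 * tp + fp + fn)
    return out


def icc(table: RatingsTable, form: str = "ICC2_1") -> ICCResult:
    """Two-way random, absolute agreement, single-measure ICC with its
    mean-square components (for auditability)."""
    if form != "ICC2_1":
        raise ValueError(f"unsupported ICC form {form!r}")
    x = table.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = 1.0 if denom == 0.0 else float((msr - mse) / denom)
    return ICCResult(estimate=est, form="ICC(2,1) two-way random, absolute "
                     "agreement, single measures",
                     ms_rows=float(msr), ms_cols=float(msc),
                     ms_error=float(mse), n_targets=n, n_raters=k)


def label_volumes_table(cases_a: list[LabelVolume], cases_b: list[LabelVolume],
                        scheme: LabelScheme | None = None) -> RatingsTable:
    """Build the (case x label) -> rater table of per-label volumes in mm^3,
    the quantity fed to the ICC.  Labels empty for both raters in a case are
    dropped (they would contribute degenerate zero-variance rows)."""
    scheme = scheme or default_scheme()
    rows, ids = [], []
    for ci, (a, b) in enumerate(zip(cases_a, cases_b)):
        _check_grids(a, b)
        voxel_mm3 = float(np.prod(a.spacing))
        ca = np.bincount(a.labels.ravel(), minlength=scheme.num_classes + 1)
        cb = np.bincount(b.labels.ravel(), minlength=scheme.num_classes + 1)
        for lab in range(1, scheme.num_classes + 1):
            if ca[lab] == 0 and cb[lab] == 0:
                continue
            rows.append((ca[lab] * voxel_mm3, cb[lab] * voxel_mm3))
            ids.append((ci, lab))
    return RatingsTable(values=np.array(rows, dtype=float),
                        target_ids=tuple(ids), rater_ids=("rater_a", "rater_b"))
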