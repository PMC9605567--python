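"""Smirnov-Grubbs outlier QC on per-ROI Z-scores, with model refitting.

The reference model's Z-scores are screened per ROI with the two-sided
Grubbs test at a 5% significance level (by default); outlying reference
subjects are excluded for that ROI only, the ROI's regression and reference
statistics are refitted on the retained subjects, and Z-scores are
recomputed once under the refitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .containers import SubjectRecord, VolumeTable, ZScoreTable
from .model import (
    CovariateSpec,
    HarmonizationModel,
    RoiAdjustment,
    build_design_matrix,
    fit_reference_model,
    score_cohort,
)

__all__ = [
    "RoiOutlierTrace",
    "OutlierReport",
    "grubbs_statistic",
    "grubbs_critical",
    "iterative_grubbs",
    "qc_and_refit",
]


def grubbs_statistic(values: np.ndarray) -> tuple[float, int]:
    """Two-sided Grubbs statistic G = max|v - mean| / sd and its argmax.

    Sample standard deviation (ddof=1). Ties broken by lowest index.
    Requires n >= 3 and non-zero spread.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError(f"Grubbs test requires at least 3 values, got {v.size}")
    if not np.isfinite(v).all():
        raise ValueError("Grubbs test requires finite values")
    sd = v.std(ddof=1)
    if sd == 0.0:
        raise ValueError("Grubbs test undefined for zero-variance sample")
    dev = np.abs(v - v.mean())
    idx = int(np.argmax(dev))  # argmax returns the lowest maximizing index
    return float(dev[idx] / sd), idx


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value at significance ``alpha``.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t on n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError(f"Grubbs critical value requires n >= 3, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


@dataclass
class RoiOutlierTrace:
    """Exclusion trace for one ROI: ids in exclusion order, the Grubbs
    statistic and critical value at each step, and any early-stop warning."""

    excluded: list[int] = field(default_factory=list)
    statistics: list[float] = field(default_factory=list)
    criticals: list[float] = field(default_factory=list)
    warning: str | None = None


def iterative_grubbs(
    values: np.ndarray, alpha: float = 0.05, min_remaining: int = 3
) -> RoiOutlierTrace:
    """Repeatedly apply the Grubbs test, excluding the most extreme point
    while it exceeds the critical value.

    Returns original indices in exclusion order. Stops, recording a
    warning, if fewer than ``min_remaining`` values would remain testable.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"iterative Grubbs requires at least 3 values, got {v.size}")
    trace = RoiOutlierTrace()
    remaining = np.arange(v.size)
    while True:
        if remaining.size < min_remaining:
            trace.warning = (
                f"stopped with {remaining.size} values remaining (< {min_remaining})"
            )
            break
        sub = v[remaining]
        if sub.std(ddof=1) == 0.0:
            break
        g, local_idx = grubbs_statistic(sub)
        crit = grubbs_critical(remaining.size, alpha)
        if g <= crit:
            break
        trace.excluded.append(int(remaining[local_idx]))
        trace.statistics.append(g)
        trace.criticals.append(crit)
        remaining = np.delete(remaining, local_idx)
    return trace


@dataclass
class OutlierReport:
    """Per-ROI Grubbs exclusion traces for one QC pass."""

    alpha: float
    traces: dict[str, RoiOutlierTrace]
    subject_ids: list[str]

    def excluded_subjects(self, roi: str) -> list[str]:
        return [self.subject_ids[i] for i in self.traces[roi].excluded]

    @property
    def n_excluded(self) -> int:
        return sum(len(t.excluded) for t in self.traces.values())

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "rois": {
                roi: {
                    "excluded_subjects": self.excluded_subjects(roi),
                    "grubbs_statistics": t.statistics,
                    "critical_values": t.criticals,
                    "warning": t.warning,
                }
                for roi, t in self.traces.items()
                if t.excluded or t.warning
            },
        }


def _refit_roi(
    volumes: VolumeTable,
    cohort: list[SubjectRecord],
    spec: CovariateSpec,
    roi: str,
    keep: np.ndarray,
) -> tuple[float, np.ndarray, float, RoiAdjustment]:
    """Single-ROI OLS refit on retained subjects; reference stats recomputed
    over the retained rows."""
    j = volumes.column_index(roi)
    kept = [cohort[i] for i in np.flatnonzero(keep)]
    X = build_design_matrix(kept, spec)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(
            f"ROI {roi!r}: only {n} subjects remain after outlier exclusion (need >= {p + 2})"
        )
    Xa = np.column_stack([np.ones(n), X])
    y = np.log10(volumes.volumes[keep, j])
    coef, _, _, _ = np.linalg.lstsq(Xa, y, rcond=None)
    resid = y - Xa @ coef
    sigma2 = float(resid @ resid) / (n - p - 1)
    excluded_ids = [cohort[i].subject_id for i in np.flatnonzero(~keep)]
    adj = RoiAdjustment(
        n=n,
        xbar=X.mean(axis=0),
        cov=np.atleast_2d(np.cov(X, rowvar=False, ddof=1)),
        excluded_subjects=excluded_ids,
    )
    return float(coef[0]), coef[1:], sigma2, adj


def qc_and_refit(
    volumes: VolumeTable,
    subjects: list[SubjectRecord],
    spec: CovariateSpec | None = None,
    alpha: float = 0.05,
    max_cycles: int = 1,
) -> tuple[HarmonizationModel, ZScoreTable, OutlierReport]:
    """Fit, screen reference Z-scores per ROI with iterative Grubbs, refit
    affected ROIs without their outliers, and rescore.

    One exclusion-refit cycle by default (exclude -> refit -> final Z);
    ``max_cycles > 1`` repeats the cycle until no new exclusions appear
    (the no-new-outlier case is a fixed point). Exclusions are per-ROI,
    never whole-subject: a subject outlying in one ROI still supports the
    reference model of every other ROI.
    """
    spec = spec or CovariateSpec()
    model = fit_reference_model(volumes, subjects, spec)
    by_id = {s.subject_id: s for s in subjects}
    cohort = [by_id[sid] for sid in volumes.subject_ids]
    ztable = score_cohort(model, cohort, volumes)

    traces: dict[str, RoiOutlierTrace] = {r: RoiOutlierTrace() for r in volumes.roi_names}
    excluded: dict[str, set[int]] = {r: set() for r in volumes.roi_names}

    for _cycle in range(max_cycles):
        new_exclusions = 0
        for roi in volumes.roi_names:
            jcol = ztable.roi_names.index(roi)
            if model.sigma2[model.roi_index(roi)] <= 1e-20:
                continue  # exact fit: residuals are rounding noise, not outliers
            active = np.array(
                [i not in excluded[roi] for i in range(len(cohort))]
            ) & ~np.isnan(ztable.z[:, jcol])
            idx = np.flatnonzero(active)
            if idx.size < 3:
                continue
            t = iterative_grubbs(ztable.z[idx, jcol], alpha=alpha)
            for k, local in enumerate(t.excluded):
                traces[roi].excluded.append(int(idx[local]))
                traces[roi].statistics.append(t.statistics[k])
                traces[roi].criticals.append(t.criticals[k])
                excluded[roi].add(int(idx[local]))
                new_exclusions += 1
            if t.warning:
                traces[roi].warning = t.warning
        if new_exclusions == 0:
            break
        for roi, excl in excluded.items():
            if not excl:
                continue
            keep = np.ones(len(cohort), dtype=bool)
            keep[list(excl)] = False
            j = model.roi_index(roi)
            b0, b, s2, adj = _refit_roi(volumes, cohort, spec, roi, keep)
            model.intercepts[j] = b0
            model.slopes[j] = b
            model.sigma2[j] = s2
            model.roi_adjustments[roi] = adj
        ztable = score_cohort(model, cohort, volumes)

    report = OutlierReport(alpha=alpha, traces=traces, subject_ids=list(volumes.subject_ids))
    return model, ztable, report
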