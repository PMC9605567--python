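"""Harmonization and discrimination metrics.

Harmonization quality is quantified by two-sample Kolmogorov-Smirnov tests
between covariate subgroups (1.5 T vs 3 T, male vs female) of the Z-score
distribution, per ROI. Discriminative power of an ROI's Z for a diagnostic
contrast (e.g. AD vs NC) is summarized by ROC AUC — with the orientation
"lower Z indicates disease", so AUC = P(Z_disease < Z_control) with ties
counted half — and by the balanced accuracy at the in-sample optimal
threshold. Age-trend regressions with 95% confidence bands and kernel
density estimates of Z support the customary visual summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .containers import Group, SubjectRecord, VolumeTable, ZScoreTable

__all__ = [
    "KSResult",
    "ROCResult",
    "AgeTrend",
    "ks_two_sample",
    "subgroup_separation_report",
    "roc_auc",
    "roc_curve_points",
    "roc_result",
    "balanced_accuracy_optimal",
    "discrimination_report",
    "age_trend",
    "kdef",
]

# below this combined size the exact two-sample KS null is used
_KS_EXACT_MAX_N = 25


@dataclass(frozen=True)
class KSResult:
    """Two-sample KS outcome: sup-distance D, p-value, rejection flag at
    the chosen alpha, and the two group sizes."""

    d: float
    p_value: float
    rejected: bool
    alpha: float
    n_a: int
    n_b: int


def ks_two_sample(a: np.ndarray, b: np.ndarray, alpha: float = 0.05) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum over pooled points of |ECDF_a - ECDF_b|; the p-value
    is asymptotic except for small combined samples, where the exact null
    distribution is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_two_sample requires non-empty samples")
    method = "exact" if a.size + b.size < _KS_EXACT_MAX_N else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    p = float(res.pvalue)
    return KSResult(
        d=float(res.statistic),
        p_value=p,
        rejected=bool(p < alpha),
        alpha=alpha,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def subgroup_separation_report(
    ztable: ZScoreTable,
    subjects: list[SubjectRecord],
    split_by: str = "field_strength",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, int]:
    """Per-ROI KS comparison of Z distributions between the two levels of a
    binary covariate.

    Returns a per-ROI table (D, p, rejected, subgroup sizes) and the count
    of ROIs where the null of a common distribution is rejected at
    ``alpha``. No multiple-testing correction is applied: rejections are
    counted at the per-ROI level.
    """
    if split_by not in ("field_strength", "sex"):
        raise ValueError(f"split_by must be 'field_strength' or 'sex', got {split_by!r}")
    by_id = {s.subject_id: s for s in subjects}
    codes = np.array(
        [getattr(by_id[sid], split_by) for sid in ztable.subject_ids], dtype=int
    )
    rows = []
    for j, roi in enumerate(ztable.roi_names):
        scored = ztable.mask[:, j] == "scored"
        za = ztable.z[scored & (codes == 0), j]
        zb = ztable.z[scored & (codes == 1), j]
        if za.size == 0 or zb.size == 0:
            raise ValueError(
                f"empty {split_by} subgroup for ROI {roi!r}; both levels must be present"
            )
        res = ks_two_sample(za, zb, alpha=alpha)
        rows.append(
            {
                "roi": roi,
                "D": res.d,
                "p_value": res.p_value,
                "rejected": res.rejected,
                "n_0": res.n_a,
                "n_1": res.n_b,
            }
        )
    table = pd.DataFrame(rows).set_index("roi")
    return table, int(table["rejected"].sum())


def roc_auc(scores_disease: np.ndarray, scores_control: np.ndarray) -> float:
    """AUC for discriminating disease from control by low Z.

    Equals the Mann-Whitney U statistic normalized by n1*n2:
    P(Z_disease < Z_control) + P(Z_disease = Z_control)/2, so values above
    0.5 indicate the disease group sits at lower (more atrophied) Z.
    """
    d = np.asarray(scores_disease, dtype=float)
    c = np.asarray(scores_control, dtype=float)
    if d.size == 0 or c.size == 0:
        raise ValueError("roc_auc requires non-empty groups")
    u = stats.mannwhitneyu(c, d, alternative="two-sided").statistic  # #(c > d) + ties/2
    return float(u) / (d.size * c.size)


def roc_curve_points(
    scores_disease: np.ndarray, scores_control: np.ndarray
) -> np.ndarray:
    """Ordered (FPR, TPR) points of the ROC curve for the rule
    "disease if Z < threshold", thresholds swept over all data values."""
    d = np.asarray(scores_disease, dtype=float)
    c = np.asarray(scores_control, dtype=float)
    thresholds = np.concatenate([[-np.inf], np.unique(np.concatenate([d, c])), [np.inf]])
    pts = [
        ((c < t).mean() if t != -np.inf else 0.0, (d < t).mean() if t != -np.inf else 0.0)
        for t in thresholds
    ]
    return np.array(pts)


def balanced_accuracy_optimal(
    scores_disease: np.ndarray, scores_control: np.ndarray
) -> tuple[float, float]:
    """(threshold, balanced accuracy) maximizing (sensitivity+specificity)/2
    for the rule "disease if Z < threshold".

    Thresholds are scanned at midpoints between consecutive pooled sorted
    unique scores (an in-sample, Youden-style optimum; optimistic relative
    to held-out use). Lowest threshold wins ties.
    """
    d = np.asarray(scores_disease, dtype=float)
    c = np.asarray(scores_control, dtype=float)
    if d.size == 0 or c.size == 0:
        raise ValueError("balanced_accuracy_optimal requires non-empty groups")
    u = np.unique(np.concatenate([d, c]))
    if u.size == 1:
        return float(u[0]), 0.5
    # interior midpoints plus one threshold below and above everything, so
    # the degenerate all-control / all-disease rules (BA 0.5) are reachable
    mids = np.concatenate([[u[0] - 1.0], (u[:-1] + u[1:]) / 2.0, [u[-1] + 1.0]])
    sens = (d[:, None] < mids[None, :]).mean(axis=0)
    spec = (c[:, None] >= mids[None, :]).mean(axis=0)
    ba = (sens + spec) / 2.0
    best = int(np.argmax(ba))  # argmax takes the lowest index = lowest threshold
    return float(mids[best]), float(ba[best])


@dataclass(frozen=True)
class ROCResult:
    """Per-ROI discrimination summary. The AUC equals the trapezoidal area
    under the (FPR, TPR) curve points."""

    auc: float
    balanced_accuracy: float
    optimal_threshold: float
    curve: np.ndarray


def roc_result(scores_disease: np.ndarray, scores_control: np.ndarray) -> ROCResult:
    """Full ROC summary (AUC, curve, optimal balanced accuracy) for one
    disease-vs-control score contrast."""
    auc = roc_auc(scores_disease, scores_control)
    thr, ba = balanced_accuracy_optimal(scores_disease, scores_control)
    return ROCResult(
        auc=auc,
        balanced_accuracy=ba,
        optimal_threshold=thr,
        curve=roc_curve_points(scores_disease, scores_control),
    )


def discrimination_report(
    ztable: ZScoreTable,
    subjects: list[SubjectRecord],
    group_disease: str | Group,
    group_control: str | Group,
    min_auc: float | None = None,
) -> pd.DataFrame:
    """Per-ROI AUC and optimal balanced accuracy for a diagnostic contrast,
    sorted descending by AUC; optionally filtered at an AUC floor."""
    gd = group_disease if isinstance(group_disease, Group) else Group.parse(group_disease)
    gc = group_control if isinstance(group_control, Group) else Group.parse(group_control)
    by_id = {s.subject_id: s for s in subjects}
    groups = np.array([by_id[sid].group.value for sid in ztable.subject_ids])
    if gd.value not in groups:
        raise ValueError(f"no subjects with group label {gd.value!r} in the Z table")
    if gc.value not in groups:
        raise ValueError(f"no subjects with group label {gc.value!r} in the Z table")
    rows = []
    for j, roi in enumerate(ztable.roi_names):
        scored = ztable.mask[:, j] == "scored"
        zd = ztable.z[scored & (groups == gd.value), j]
        zc = ztable.z[scored & (groups == gc.value), j]
        auc = roc_auc(zd, zc)
        thr, ba = balanced_accuracy_optimal(zd, zc)
        rows.append(
            {"roi": roi, "auc": auc, "balanced_accuracy": ba, "optimal_threshold": thr}
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("auc", ascending=False, kind="mergesort")
        .set_index("roi")
    )
    if min_auc is not None:
        table = table[table["auc"] >= min_auc]
    return table


@dataclass(frozen=True)
class AgeTrend:
    """Simple log10-volume-on-age regression with a pointwise 95% CI band
    for the mean response over an age grid."""

    slope: float
    intercept: float
    slope_stderr: float
    ages: np.ndarray
    fitted: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    correlation: float


def age_trend(
    volumes: VolumeTable,
    subjects: list[SubjectRecord],
    roi: str,
    age_grid: np.ndarray | None = None,
    alpha: float = 0.05,
) -> AgeTrend:
    """Regress log10 volume of one ROI on age with a mean-response CI band.

    Gray-matter ROIs typically show a negative age slope (age-related
    atrophy); the ``correlation`` field reports the Pearson correlation so
    the sign is directly inspectable.
    """
    by_id = {s.subject_id: s for s in subjects}
    j = volumes.column_index(roi)
    ages = np.array([by_id[sid].age for sid in volumes.subject_ids], dtype=float)
    y = np.log10(volumes.volumes[:, j])
    ok = ~np.isnan(y)
    ages, y = ages[ok], y[ok]
    if ages.size < 3:
        raise ValueError("age_trend requires at least 3 subjects")
    if np.ptp(ages) == 0.0:
        raise ValueError("degenerate age distribution: all ages identical")
    X = np.column_stack([np.ones(ages.size), ages])
    fit = sm.OLS(y, X).fit()
    if age_grid is None:
        age_grid = np.linspace(ages.min(), ages.max(), 100)
    grid = np.asarray(age_grid, dtype=float)
    pred = fit.get_prediction(np.column_stack([np.ones(grid.size), grid]))
    ci = pred.conf_int(alpha=alpha)
    corr = float(np.corrcoef(ages, y)[0, 1]) if y.std() > 0 else 0.0
    return AgeTrend(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_stderr=float(fit.bse[1]),
        ages=np.asarray(age_grid, dtype=float),
        fitted=pred.predicted_mean,
        ci_low=ci[:, 0],
        ci_high=ci[:, 1],
        correlation=corr,
    )


def kdef(
    z_values: np.ndarray, grid: np.ndarray | None = None, gridsize: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Kernel density estimate of a Z-score sample (Gaussian kernel,
    Silverman bandwidth) evaluated on a grid.

    The returned density integrates to 1 over the default grid to within
    about 1%. Requires n >= 2 and non-zero variance.
    """
    v = np.asarray(z_values, dtype=float)
    if v.size < 2:
        raise ValueError("kdef requires at least 2 values")
    if v.std() == 0.0:
        raise ValueError("kdef undefined for zero-variance sample")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    if grid is None:
        h = float(np.sqrt(kde.covariance[0, 0]))
        grid = np.linspace(v.min() - 5 * h, v.max() + 5 * h, gridsize)
    grid = np.asarray(grid, dtype=float)
    return grid, kde(grid)
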