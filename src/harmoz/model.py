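"""Normative general linear model and harmonized Z-scores.

The reference model regresses, per ROI, log10 volume on a subject-level
covariate row (age, field strength, sex, log10 eTIV, or any ordered subset):

    log10 V_ij = beta0_j + beta_j . x_i + eps_ij

fitted by ordinary least squares on a cognitively normal (NC) reference
cohort. A subject is then scored with the prediction-studentized residual

    Z_ij = eps_ij / sqrt((1 + 1/N + q_i) * sigma2_j)

where ``sigma2_j`` is the unbiased residual variance SSE/(N - p - 1) and

    q_i = (x_i - xbar)' Sigma^{-1} (x_i - xbar) / (N - 1)

with ``Sigma`` the sample covariance of the N reference covariate rows.
Under this reading ``1/N + q_i`` is exactly the hat-matrix leverage of the
intercept-augmented design, so Z is the classical studentized residual for
predicting a new observation: approximately standard normal in a held-out
normal subject when N is large, whatever the subject's age, sex, scanner
field strength or head size. Z below -2 flags significant atrophy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .containers import (
    MASK_EXCLUDED,
    MASK_MISSING,
    MASK_SCORED,
    SubjectRecord,
    VolumeTable,
    ZScoreTable,
)

__all__ = [
    "COVARIATE_NAMES",
    "CovariateSpec",
    "RoiAdjustment",
    "HarmonizationModel",
    "build_design_row",
    "build_design_matrix",
    "fit_reference_model",
    "leverage_term",
    "compute_zscore",
    "score_cohort",
    "classify_atrophy",
    "ATROPHY_THRESHOLD",
]

COVARIATE_NAMES = ("age", "field_strength", "sex", "log10_etiv")

#: Z threshold below which an ROI is called significantly atrophied.
ATROPHY_THRESHOLD = -2.0


@dataclass(frozen=True)
class CovariateSpec:
    """Ordered subset of covariates entering the reference model.

    The conventional model variants are exposed by :meth:`variant`:
    (a) age only; (b) age + field strength; (c) age + field strength +
    log10 eTIV; (d) age + field strength + log10 eTIV + sex. Variant (d)
    is the package default.
    """

    included: tuple[str, ...] = ("age", "field_strength", "log10_etiv", "sex")

    def __post_init__(self) -> None:
        if len(self.included) == 0:
            raise ValueError("CovariateSpec must include at least one covariate")
        object.__setattr__(self, "included", tuple(self.included))
        unknown = [c for c in self.included if c not in COVARIATE_NAMES]
        if unknown:
            raise ValueError(f"unknown covariates {unknown}; valid names: {COVARIATE_NAMES}")
        if len(set(self.included)) != len(self.included):
            raise ValueError("duplicate covariates in spec")

    @classmethod
    def variant(cls, letter: str) -> "CovariateSpec":
        variants = {
            "a": ("age",),
            "b": ("age", "field_strength"),
            "c": ("age", "field_strength", "log10_etiv"),
            "d": ("age", "field_strength", "log10_etiv", "sex"),
        }
        try:
            return cls(variants[letter.lower()])
        except KeyError:
            raise ValueError(f"unknown model variant {letter!r}; use one of a, b, c, d") from None

    @property
    def size(self) -> int:
        return len(self.included)


def build_design_row(subject: SubjectRecord, spec: CovariateSpec) -> np.ndarray:
    """Covariate row x_i for one subject, ordered per the spec.

    eTIV enters on the log10 scale; sex and field strength as their 0/1
    codes; age in years.
    """
    values = {
        "age": float(subject.age),
        "field_strength": float(subject.field_strength),
        "sex": float(subject.sex),
        "log10_etiv": math.log10(subject.etiv),
    }
    return np.array([values[c] for c in spec.included], dtype=float)


def build_design_matrix(subjects: list[SubjectRecord], spec: CovariateSpec) -> np.ndarray:
    return np.vstack([build_design_row(s, spec) for s in subjects])


@dataclass
class RoiAdjustment:
    """Per-ROI reference statistics after outlier exclusion.

    Present only for ROIs where QC removed subjects; scoring then uses
    these in place of the cohort-wide N, xbar and Sigma.
    """

    n: int
    xbar: np.ndarray
    cov: np.ndarray
    excluded_subjects: list[str]


@dataclass
class HarmonizationModel:
    """Fitted per-ROI normative model plus shared reference statistics.

    Attributes
    ----------
    spec : covariates in the design row, in order.
    roi_names : ROI catalog, in volume-table column order.
    intercepts, slopes, sigma2 : per-ROI beta0_j, beta_j (shape (R, p)) and
        unbiased residual variance.
    n_ref : reference cohort size N.
    xbar, cov : covariate mean vector and sample covariance (ddof=1) over
        the N reference rows.
    roi_adjustments : per-ROI overrides created by outlier QC.
    """

    spec: CovariateSpec
    roi_names: list[str]
    intercepts: np.ndarray
    slopes: np.ndarray
    sigma2: np.ndarray
    n_ref: int
    xbar: np.ndarray
    cov: np.ndarray
    roi_adjustments: dict[str, RoiAdjustment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = self.spec.size
        r = len(self.roi_names)
        self.intercepts = np.asarray(self.intercepts, dtype=float).reshape(r)
        self.slopes = np.asarray(self.slopes, dtype=float).reshape(r, p)
        self.sigma2 = np.asarray(self.sigma2, dtype=float).reshape(r)
        self.xbar = np.asarray(self.xbar, dtype=float).reshape(p)
        self.cov = np.asarray(self.cov, dtype=float).reshape(p, p)
        if (self.sigma2 < 0).any():
            raise ValueError("negative residual variance")
        if self.n_ref < p + 2:
            raise ValueError(f"reference size N={self.n_ref} below minimum p+2={p + 2}")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariate covariance matrix is not symmetric")

    def roi_index(self, roi: str) -> int:
        try:
            return self.roi_names.index(roi)
        except ValueError:
            raise KeyError(f"ROI {roi!r} not in model") from None

    def reference_stats(self, roi: str | None = None) -> tuple[int, np.ndarray, np.ndarray]:
        """(N, xbar, Sigma) used in the Z denominator for this ROI."""
        if roi is not None and roi in self.roi_adjustments:
            adj = self.roi_adjustments[roi]
            return adj.n, adj.xbar, adj.cov
        return self.n_ref, self.xbar, self.cov


def _check_design_rank(X: np.ndarray, spec: CovariateSpec) -> None:
    n, p = X.shape
    const = [spec.included[j] for j in range(p) if np.ptp(X[:, j]) == 0.0]
    if const:
        raise ValueError(
            f"degenerate design: covariate(s) {const} are constant in the reference "
            "cohort (e.g. a single-field-strength cohort); remove them from the covariate spec"
        )
    Xa = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xa) < p + 1:
        raise ValueError(
            "rank-deficient design: covariates are collinear; remove a redundant "
            "covariate from the spec"
        )


def fit_reference_model(
    volumes: VolumeTable,
    subjects: list[SubjectRecord],
    spec: CovariateSpec | None = None,
) -> HarmonizationModel:
    """Fit the per-ROI OLS normative model on a reference (NC) cohort.

    Every subject in the volume table must have a metadata record; rows are
    taken in volume-table order. Missing (NaN) volumes are not permitted in
    reference fitting.
    """
    spec = spec or CovariateSpec()
    by_id = {s.subject_id: s for s in subjects}
    missing = [sid for sid in volumes.subject_ids if sid not in by_id]
    if missing:
        raise ValueError(f"no metadata for volume-table subject(s): {missing[:5]}")
    cohort = [by_id[sid] for sid in volumes.subject_ids]

    if np.isnan(volumes.volumes).any():
        i, j = map(int, np.argwhere(np.isnan(volumes.volumes))[0])
        raise ValueError(
            f"missing volume for subject {volumes.subject_ids[i]!r}, ROI "
            f"{volumes.roi_names[j]!r}: reference fitting requires complete tables"
        )

    n, p = len(cohort), spec.size
    if n < p + 2:
        raise ValueError(f"reference cohort size {n} below minimum p+2={p + 2}")

    X = build_design_matrix(cohort, spec)
    _check_design_rank(X, spec)
    Xa = np.column_stack([np.ones(n), X])
    Y = np.log10(volumes.volumes)

    coef, _, _, _ = np.linalg.lstsq(Xa, Y, rcond=None)
    resid = Y - Xa @ coef
    sse = np.einsum("ij,ij->j", resid, resid)
    sigma2 = sse / (n - p - 1)

    return HarmonizationModel(
        spec=spec,
        roi_names=list(volumes.roi_names),
        intercepts=coef[0],
        slopes=coef[1:].T,
        sigma2=sigma2,
        n_ref=n,
        xbar=X.mean(axis=0),
        cov=np.atleast_2d(np.cov(X, rowvar=False, ddof=1)),
    )


def _solve_cov(cov: np.ndarray, d: np.ndarray, spec: CovariateSpec) -> np.ndarray:
    # cond check catches near-singular Sigma before solve returns garbage
    if np.linalg.cond(cov) > 1e12:
        w, v = np.linalg.eigh(cov)
        worst = v[:, int(np.argmin(np.abs(w)))]
        names = [spec.included[j] for j in np.argsort(-np.abs(worst))[:2]]
        raise ValueError(
            f"singular covariate covariance matrix; covariates {names} are "
            "collinear or constant — remove one from the spec"
        )
    return np.linalg.solve(cov, d)


def leverage_term(
    model: HarmonizationModel, x: np.ndarray, roi: str | None = None
) -> float:
    """Covariate-distance term q_i = (x - xbar)' Sigma^{-1} (x - xbar)/(N-1).

    ``1/N + q_i`` equals the hat-matrix leverage of x in the
    intercept-augmented reference design; it inflates the Z denominator for
    subjects far from the reference-cohort covariate centre.
    """
    n, xbar, cov = model.reference_stats(roi)
    x = np.asarray(x, dtype=float).reshape(model.spec.size)
    d = x - xbar
    q = float(d @ _solve_cov(cov, d, model.spec)) / (n - 1)
    return max(q, 0.0)


def compute_zscore(
    model: HarmonizationModel, subject: SubjectRecord, volume: float, roi: str
) -> float:
    """Harmonized Z for one subject and ROI.

    The same denominator (prediction standard error, including the
    1 + 1/N + q_i leverage inflation) is used for reference-cohort and new
    subjects alike.
    """
    if not (math.isfinite(volume) and volume > 0):
        raise ValueError(f"volume must be finite and positive, got {volume}")
    j = model.roi_index(roi)
    x = build_design_row(subject, model.spec)
    eps = math.log10(volume) - (model.intercepts[j] + float(model.slopes[j] @ x))
    n, _, _ = model.reference_stats(roi)
    q = leverage_term(model, x, roi)
    s2 = float(model.sigma2[j])
    if s2 == 0.0:
        if abs(eps) < 1e-12:
            return 0.0
        raise ValueError(
            f"degenerate model for ROI {roi!r}: zero residual variance but non-zero residual"
        )
    return eps / math.sqrt((1.0 + 1.0 / n + q) * s2)


def score_cohort(
    model: HarmonizationModel,
    subjects: list[SubjectRecord],
    volumes: VolumeTable,
) -> ZScoreTable:
    """Vectorized harmonized-Z scoring of a cohort.

    Cellwise identical to :func:`compute_zscore`. Missing volumes yield
    ``missing`` mask cells; reference subjects excluded by QC for an ROI are
    flagged ``excluded_outlier`` there (their Z under the refitted model is
    still reported).
    """
    unknown = [r for r in volumes.roi_names if r not in model.roi_names]
    if unknown:
        raise KeyError(f"ROI column(s) not in model: {unknown[:5]}")
    by_id = {s.subject_id: s for s in subjects}
    missing = [sid for sid in volumes.subject_ids if sid not in by_id]
    if missing:
        raise ValueError(f"no metadata for volume-table subject(s): {missing[:5]}")
    cohort = [by_id[sid] for sid in volumes.subject_ids]

    n_sub = len(cohort)
    X = build_design_matrix(cohort, model.spec)
    logv = np.log10(volumes.volumes)

    cols = [model.roi_index(r) for r in volumes.roi_names]
    pred = model.intercepts[cols] + X @ model.slopes[cols].T
    eps = logv - pred

    # leverage under the shared reference stats, reused for unadjusted ROIs
    d = X - model.xbar
    q_shared = np.einsum(
        "ij,ij->i", d, np.linalg.solve(model.cov, d.T).T
    ) / (model.n_ref - 1)
    q_shared = np.maximum(q_shared, 0.0)

    z = np.empty((n_sub, len(cols)))
    mask = np.full((n_sub, len(cols)), MASK_SCORED, dtype=object)
    for k, roi in enumerate(volumes.roi_names):
        n, xbar, cov = model.reference_stats(roi)
        if roi in model.roi_adjustments:
            dr = X - xbar
            q = np.einsum("ij,ij->i", dr, np.linalg.solve(cov, dr.T).T) / (n - 1)
            q = np.maximum(q, 0.0)
        else:
            q = q_shared
        s2 = model.sigma2[cols[k]]
        with np.errstate(invalid="ignore"):
            z[:, k] = eps[:, k] / np.sqrt((1.0 + 1.0 / n + q) * s2)
        excl = set(model.roi_adjustments[roi].excluded_subjects) if roi in model.roi_adjustments else set()
        for i, sid in enumerate(volumes.subject_ids):
            if np.isnan(logv[i, k]):
                mask[i, k] = MASK_MISSING
            elif sid in excl:
                mask[i, k] = MASK_EXCLUDED
    return ZScoreTable(
        subject_ids=list(volumes.subject_ids),
        roi_names=list(volumes.roi_names),
        z=z,
        mask=mask,
    )


def classify_atrophy(z: float) -> str:
    """'atrophied' if Z < -2 (strict), else 'normal'."""
    if not math.isfinite(z):
        raise ValueError(f"Z must be finite, got {z}")
    return "atrophied" if z < ATROPHY_THRESHOLD else "normal"
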