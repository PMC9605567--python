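"""Normative model: design rows, OLS fit, leverage, Z-scores."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import harmoz
from harmoz import (
    CovariateSpec,
    SubjectRecord,
    VolumeTable,
    build_design_row,
    classify_atrophy,
    compute_zscore,
    fit_reference_model,
    leverage_term,
    score_cohort,
)
from harmoz.model import build_design_matrix


def _subject(sid="s", age=70.0, sex=0, field=0, etiv=1e6, group="other"):
    return SubjectRecord(sid, age, sex, field, etiv, group)


class TestDesignRow:
    def test_full_spec_ordering_and_log10_etiv(self):
        x = build_design_row(_subject(age=70, sex=0, field=0, etiv=1e6), CovariateSpec())
        np.testing.assert_allclose(x, [70.0, 0.0, 6.0, 0.0])

    def test_age_only_projection(self):
        x = build_design_row(_subject(age=70), CovariateSpec(("age",)))
        np.testing.assert_allclose(x, [70.0])

    @given(
        st.floats(40, 95),
        st.integers(0, 1),
        st.integers(0, 1),
        st.floats(1e6, 2e6),
    )
    def test_entries_match_independent_recomputation(self, age, sex, field, etiv):
        spec = CovariateSpec(("sex", "log10_etiv", "age", "field_strength"))
        x = build_design_row(_subject(age=age, sex=sex, field=field, etiv=etiv), spec)
        expected = [float(sex), math.log10(etiv), float(age), float(field)]
        np.testing.assert_allclose(x, expected)

    def test_variants(self):
        assert CovariateSpec.variant("a").included == ("age",)
        assert CovariateSpec.variant("d").included == (
            "age", "field_strength", "log10_etiv", "sex",
        )
        with pytest.raises(ValueError):
            CovariateSpec.variant("e")

    def test_spec_rejects_unknown_and_empty(self):
        with pytest.raises(ValueError):
            CovariateSpec(("age", "scanner_vendor"))
        with pytest.raises(ValueError):
            CovariateSpec(())


def _cohort_on_surface(n, rng, beta0=3.5, betas=(-0.001, -0.02, 0.01, 0.7), noise=0.0):
    """Subjects + volumes generated exactly from the variant-(d) surface."""
    subjects, rows = [], []
    for i in range(n):
        s = _subject(
            f"s{i}",
            age=float(rng.uniform(45, 90)),
            sex=int(rng.integers(2)),
            field=int(rng.integers(2)),
            etiv=float(rng.uniform(1.2e6, 1.8e6)),
        )
        x = build_design_row(s, CovariateSpec())
        logv = beta0 + float(np.dot(betas, x)) + rng.normal(0, noise)
        subjects.append(s)
        rows.append([10.0 ** logv])
    return subjects, VolumeTable([s.subject_id for s in subjects], ["roi"], rows)


class TestFit:
    def test_noiseless_recovery_to_machine_precision(self, rng):
        subjects, volumes = _cohort_on_surface(50, rng)
        m = fit_reference_model(volumes, subjects)
        np.testing.assert_allclose(m.intercepts[0], 3.5, atol=1e-8)
        np.testing.assert_allclose(m.slopes[0], [-0.001, -0.02, 0.01, 0.7], atol=1e-9)
        assert m.sigma2[0] < 1e-20

    def test_closed_form_simple_regression_n6(self):
        # one covariate (age), hand-enumerable values
        ages = [50.0, 55.0, 60.0, 65.0, 70.0, 75.0]
        logv = [3.50, 3.48, 3.47, 3.44, 3.42, 3.40]
        subjects = [_subject(f"s{i}", age=a) for i, a in enumerate(ages)]
        volumes = VolumeTable(
            [s.subject_id for s in subjects], ["roi"], [[10.0 ** v] for v in logv]
        )
        m = fit_reference_model(volumes, subjects, CovariateSpec(("age",)))
        # independent closed-form simple regression
        xb, yb = sum(ages) / 6, sum(logv) / 6
        sxx = sum((a - xb) ** 2 for a in ages)
        sxy = sum((a - xb) * (y - yb) for a, y in zip(ages, logv))
        slope = sxy / sxx
        intercept = yb - slope * xb
        sse = sum((y - intercept - slope * a) ** 2 for a, y in zip(ages, logv))
        np.testing.assert_allclose(m.slopes[0, 0], slope, rtol=1e-10)
        np.testing.assert_allclose(m.intercepts[0], intercept, rtol=1e-10)
        np.testing.assert_allclose(m.sigma2[0], sse / 4, rtol=1e-8)

    def test_agrees_with_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        subjects, volumes = _cohort_on_surface(120, rng, noise=0.05)
        m = fit_reference_model(volumes, subjects)
        X = sm.add_constant(build_design_matrix(subjects, CovariateSpec()))
        fit = sm.OLS(np.log10(np.asarray(volumes.volumes)[:, 0]), X).fit()
        np.testing.assert_allclose(m.intercepts[0], fit.params[0], rtol=1e-8)
        np.testing.assert_allclose(m.slopes[0], fit.params[1:], rtol=1e-8)
        np.testing.assert_allclose(m.sigma2[0], fit.mse_resid, rtol=1e-8)

    def test_parameter_recovery_within_3se(self):
        cfg = harmoz.default_config(n_rois=3)
        cfg.groups = {
            "NC_3T": cfg.groups["NC_3T"],
            "NC_1.5T": cfg.groups["NC_1.5T"],
        }
        cfg.groups["NC_3T"].size = 700
        cfg.groups["NC_1.5T"].size = 300
        subjects, volumes, truth = harmoz.simulate_cohort(cfg, seed=5)
        m = fit_reference_model(volumes, subjects)
        import statsmodels.api as sm

        X = sm.add_constant(build_design_matrix(subjects, m.spec))
        for j, roi in enumerate(m.roi_names):
            fit = sm.OLS(np.log10(np.asarray(volumes.volumes)[:, j]), X).fit()
            true = truth["rois"][roi]
            expected = [true["age_slope"], true["field_offset"], true["etiv_slope"], true["sex_offset"]]
            for k in range(4):
                assert abs(m.slopes[j, k] - expected[k]) < 3 * fit.bse[k + 1]

    def test_constant_covariate_fails_loudly(self, rng):
        subjects, volumes = _cohort_on_surface(30, rng, noise=0.01)
        all3t = [
            SubjectRecord(s.subject_id, s.age, s.sex, 0, s.etiv, s.group) for s in subjects
        ]
        with pytest.raises(ValueError, match="field_strength"):
            fit_reference_model(volumes, all3t)

    def test_missing_cells_rejected_in_reference_fit(self, rng):
        subjects, volumes = _cohort_on_surface(30, rng, noise=0.01)
        v = np.asarray(volumes.volumes).copy()
        v[3, 0] = np.nan
        volumes2 = VolumeTable(list(volumes.subject_ids), ["roi"], v)
        with pytest.raises(ValueError, match="missing volume"):
            fit_reference_model(volumes2, subjects)

    def test_too_small_cohort_rejected(self, rng):
        subjects, volumes = _cohort_on_surface(5, rng, noise=0.01)
        with pytest.raises(ValueError, match="minimum"):
            fit_reference_model(volumes, subjects)


class TestLeverage:
    def test_zero_at_covariate_centre(self, rng):
        subjects, volumes = _cohort_on_surface(40, rng, noise=0.02)
        m = fit_reference_model(volumes, subjects)
        assert leverage_term(m, m.xbar) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_closed_form_one_covariate(self, rng):
        ages = rng.uniform(45, 90, size=25)
        subjects = [_subject(f"s{i}", age=a) for i, a in enumerate(ages)]
        volumes = VolumeTable(
            [s.subject_id for s in subjects], ["roi"],
            10 ** (3.5 - 0.001 * ages[:, None] + rng.normal(0, 0.03, (25, 1))),
        )
        m = fit_reference_model(volumes, subjects, CovariateSpec(("age",)))
        x = np.array([72.5])
        expected = (72.5 - ages.mean()) ** 2 / ((25 - 1) * ages.var(ddof=1))
        assert leverage_term(m, x) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("p", [1, 2, 3, 4])
    def test_hat_matrix_identity(self, p, rng):
        """1/N + q_i equals the hat-matrix leverage of the intercept-
        augmented design for every reference row."""
        n = int(rng.integers(10, 200))
        subjects, volumes = _cohort_on_surface(n, rng, noise=0.02)
        spec = CovariateSpec(CovariateSpec().included[:p])
        m = fit_reference_model(volumes, subjects, spec)
        X = build_design_matrix(subjects, spec)
        Xa = np.column_stack([np.ones(n), X])
        H = Xa @ np.linalg.inv(Xa.T @ Xa) @ Xa.T
        for i in range(0, n, max(n // 10, 1)):
            q = leverage_term(m, X[i])
            assert 1.0 / n + q == pytest.approx(H[i, i], abs=1e-10)

    def test_singular_covariance_names_covariates(self, rng):
        subjects, volumes = _cohort_on_surface(30, rng, noise=0.02)
        m = fit_reference_model(volumes, subjects, CovariateSpec(("age", "sex")))
        m.cov[:] = np.ones((2, 2))  # force perfect collinearity
        with pytest.raises(ValueError, match="collinear"):
            leverage_term(m, np.array([70.0, 1.0]))


class TestZScore:
    def test_on_surface_volume_scores_zero(self, rng):
        subjects, volumes = _cohort_on_surface(40, rng, noise=0.03)
        m = fit_reference_model(volumes, subjects)
        s = _subject("new", age=66, sex=1, field=1, etiv=1.5e6)
        x = build_design_row(s, m.spec)
        v = 10.0 ** (m.intercepts[0] + float(m.slopes[0] @ x))
        assert compute_zscore(m, s, v, "roi") == pytest.approx(0.0, abs=1e-10)

    def test_matches_spreadsheet_recomputation_n5(self):
        """Tiny one-covariate reference; Z recomputed step by step with
        plain arithmetic, independently of the model code."""
        ages = [55.0, 60.0, 65.0, 70.0, 75.0]
        logv = [3.52, 3.50, 3.49, 3.45, 3.41]
        subjects = [_subject(f"s{i}", age=a) for i, a in enumerate(ages)]
        volumes = VolumeTable(
            [s.subject_id for s in subjects], ["roi"], [[10.0 ** y] for y in logv]
        )
        m = fit_reference_model(volumes, subjects, CovariateSpec(("age",)))

        n = 5
        xb = sum(ages) / n
        yb = sum(logv) / n
        sxx = sum((a - xb) ** 2 for a in ages)
        slope = sum((a - xb) * (y - yb) for a, y in zip(ages, logv)) / sxx
        b0 = yb - slope * xb
        sse = sum((y - b0 - slope * a) ** 2 for a, y in zip(ages, logv))
        s2 = sse / (n - 2)
        var = sxx / (n - 1)

        new_age, new_logv = 80.0, 3.35
        eps = new_logv - (b0 + slope * new_age)
        q = (new_age - xb) ** 2 / ((n - 1) * var)
        expected = eps / math.sqrt((1 + 1 / n + q) * s2)

        z = compute_zscore(m, _subject("new", age=new_age), 10.0 ** new_logv, "roi")
        assert z == pytest.approx(expected, rel=1e-10)

    def test_degenerate_zero_variance_model(self, rng):
        subjects, volumes = _cohort_on_surface(20, rng, noise=0.0)
        m = fit_reference_model(volumes, subjects)
        m.sigma2[:] = 0.0
        s = subjects[0]
        v_on = float(np.asarray(volumes.volumes)[0, 0])
        assert compute_zscore(m, s, v_on, "roi") == pytest.approx(0.0)
        with pytest.raises(ValueError, match="degenerate"):
            compute_zscore(m, s, v_on * 2, "roi")

    def test_atrophy_classification(self):
        assert classify_atrophy(-2.5) == "atrophied"
        assert classify_atrophy(0.0) == "normal"
        assert classify_atrophy(-2.0) == "normal"  # strict inequality
        with pytest.raises(ValueError):
            classify_atrophy(float("nan"))


class TestScoreCohort:
    def test_equals_scalar_loop(self, nc_reference):
        nc, vnc = nc_reference
        m = harmoz.fit_reference_model(vnc, nc)
        table = score_cohort(m, nc, vnc)
        by_id = {s.subject_id: s for s in nc}
        rng = np.random.default_rng(3)
        for i in rng.choice(len(vnc.subject_ids), size=15, replace=False):
            for j in rng.choice(len(vnc.roi_names), size=3, replace=False):
                z = compute_zscore(
                    m, by_id[vnc.subject_ids[i]], vnc.volumes[i, j], vnc.roi_names[j]
                )
                assert table.z[i, j] == pytest.approx(z, rel=1e-12)

    def test_row_permutation_equivariance(self, nc_reference):
        nc, vnc = nc_reference
        m = harmoz.fit_reference_model(vnc, nc)
        z1 = score_cohort(m, nc, vnc)
        perm = np.random.default_rng(0).permutation(len(vnc.subject_ids))
        vperm = VolumeTable(
            [vnc.subject_ids[i] for i in perm], list(vnc.roi_names), vnc.volumes[perm]
        )
        z2 = score_cohort(m, nc, vperm)
        np.testing.assert_allclose(z2.z, z1.z[perm], rtol=1e-14)

    def test_missing_cells_masked_not_fatal(self, nc_reference):
        nc, vnc = nc_reference
        m = harmoz.fit_reference_model(vnc, nc)
        v = vnc.volumes.copy()
        v[2, 1] = np.nan
        z = score_cohort(m, nc, VolumeTable(list(vnc.subject_ids), list(vnc.roi_names), v))
        assert z.mask[2, 1] == harmoz.MASK_MISSING
        assert np.isnan(z.z[2, 1])
        assert (z.mask == harmoz.MASK_SCORED).sum() == z.z.size - 1

    def test_unknown_roi_rejected(self, nc_reference):
        nc, vnc = nc_reference
        m = harmoz.fit_reference_model(vnc, nc)
        bad = VolumeTable(list(vnc.subject_ids), ["nope"], vnc.volumes[:, :1])
        with pytest.raises(KeyError, match="nope"):
            score_cohort(m, nc, bad)


@pytest.fixture(scope="module")
def fit_and_holdout():
    cfg = harmoz.default_config(n_rois=5)
    cfg.groups = {"NC_3T": cfg.groups["NC_3T"], "NC_1.5T": cfg.groups["NC_1.5T"]}
    cfg.groups["NC_3T"].size = 700
    cfg.groups["NC_1.5T"].size = 300
    ref_s, ref_v, _ = harmoz.simulate_cohort(cfg, seed=11)
    hold_s, hold_v, _ = harmoz.simulate_cohort(cfg, seed=12)
    hold_s = hold_s[:500]
    hold_v = VolumeTable(
        [s.subject_id for s in hold_s], list(hold_v.roi_names), hold_v.volumes[:500]
    )
    m = harmoz.fit_reference_model(ref_v, ref_s)
    return m, ref_s, ref_v, hold_s, hold_v


class TestCalibration:
    """Held-out NC Z-scores are approximately standard normal."""

    def test_heldout_mean_and_variance(self, fit_and_holdout):
        m, _, _, hold_s, hold_v = fit_and_holdout
        z = score_cohort(m, hold_s, hold_v)
        for j in range(len(z.roi_names)):
            col = z.z[:, j]
            assert abs(col.mean()) < 0.15  # SE(mean) ~ 0.045 at n=500
            assert 0.85 < col.var(ddof=1) < 1.15

    def test_in_sample_variance_slightly_below_one(self, fit_and_holdout):
        m, ref_s, ref_v, _, _ = fit_and_holdout
        z = score_cohort(m, ref_s, ref_v)
        for j in range(len(z.roi_names)):
            assert 0.85 < z.z[:, j].var(ddof=1) < 1.05
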