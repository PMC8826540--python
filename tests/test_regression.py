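import numpy as np
import pandas as pd
import pytest

from pulsesv import (CohortConfig, SVRegression, SVRegressionResults,
                     ValidationError, cross_validate, fit_ols, generate_cohort,
                     prune_nonsignificant)

PAPER_COEFFS = {"age": -0.34, "weight_kg": 0.38, "height_m": 40.14,
                "brSBP_mmHg": 0.47, "HR_bpm": -0.45, "cfPWV_mps": -4.23}


@pytest.fixture(scope="module")
def cohort144():
    return generate_cohort(CohortConfig(seed=3))


@pytest.fixture(scope="module")
def linear_cohort(cohort144):
    """Covariates from the synthetic cohort; response exactly linear + noise,
    with zero true effect for gender and brDBP."""
    rng = np.random.default_rng(42)
    df = cohort144.copy()
    df["height_m"] = df["height_cm"] / 100.0
    y = sum(c * df[v] for v, c in PAPER_COEFFS.items())
    df["SV_ref_mL"] = y + rng.normal(0, 8.0, len(df))
    return df


class TestFitOLS:
    def test_exact_recovery_noise_free(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x1": rng.normal(size=50), "x2": rng.normal(size=50)})
        df["y"] = 2.0 * df.x1 - 3.0 * df.x2
        res = fit_ols(df, response="y", variables=["x1", "x2"])
        assert res.params["x1"] == pytest.approx(2.0, abs=1e-10)
        assert res.params["x2"] == pytest.approx(-3.0, abs=1e-10)

    def test_row_permutation_invariance(self, linear_cohort):
        res1 = fit_ols(linear_cohort)
        shuffled = linear_cohort.sample(frac=1.0, random_state=9)
        res2 = fit_ols(shuffled)
        assert np.allclose(res1.params.to_numpy(), res2.params.to_numpy())

    def test_estimates_within_sampling_error(self):
        # known coefficients + Gaussian noise of known scale, n = 100
        rng = np.random.default_rng(7)
        n, sigma = 100, 1.5
        X = rng.normal(size=(n, 3))
        beta = np.array([1.0, -2.0, 0.5])
        y = X @ beta + rng.normal(0, sigma, n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        res = fit_ols(df, response="y", variables=["a", "b", "c"])
        cov = sigma**2 * np.linalg.inv(X.T @ X)
        se = np.sqrt(np.diag(cov))
        for i, v in enumerate(["a", "b", "c"]):
            assert abs(res.params[v] - beta[i]) < 3 * se[i]

    def test_collinear_design_named(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x1": rng.normal(size=40)})
        df["x2"] = 2.0 * df["x1"]
        df["y"] = df["x1"] + rng.normal(size=40)
        with pytest.raises(ValidationError, match="x1|x2"):
            fit_ols(df, response="y", variables=["x1", "x2"])

    def test_residuals_orthogonal_to_design(self, linear_cohort):
        res = fit_ols(linear_cohort)
        model = res.model
        resid = model.y - res.predict(linear_cohort)
        for v in model.variables:
            col = model.X[v].to_numpy()
            assert abs(np.dot(resid, col)) < 1e-8 * np.linalg.norm(col) * \
                np.linalg.norm(resid) + 1e-8


class TestPruning:
    def test_drops_true_zero_effects_and_keeps_paper_set(self, linear_cohort):
        full = fit_ols(linear_cohort)
        pruned = prune_nonsignificant(full, linear_cohort, alpha=0.05)
        assert set(pruned.dropped) == {"gender", "brDBP_mmHg"}
        assert set(pruned.retained) == set(PAPER_COEFFS)
        assert pruned.full_model is full

    def test_all_significant_model_unchanged(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x1": rng.normal(size=200), "x2": rng.normal(size=200)})
        df["y"] = 3 * df.x1 + 2 * df.x2 + rng.normal(0, 0.5, 200)
        res = fit_ols(df, response="y", variables=["x1", "x2"])
        assert prune_nonsignificant(res, df) is res

    def test_single_pass_not_iterative(self, linear_cohort):
        # pruning refits exactly once: variables significant only in the
        # refit are not re-examined, and the refit keeps all survivors
        full = fit_ols(linear_cohort)
        pruned = prune_nonsignificant(full, linear_cohort, alpha=0.05)
        assert len(pruned.retained) == len(full.retained) - len(pruned.dropped)

    def test_all_dropped_is_error(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"x1": rng.normal(size=60), "x2": rng.normal(size=60)})
        df["y"] = rng.normal(size=60)  # pure noise
        res = fit_ols(df, response="y", variables=["x1", "x2"], intercept=True)
        if (res.pvalues[["x1", "x2"]] >= 0.05).all():
            with pytest.raises(ValidationError):
                prune_nonsignificant(res, df)


class TestPredict:
    def test_printed_equation_at_cohort_means(self):
        model = SVRegressionResults.from_coefficients(PAPER_COEFFS)
        subject = {"age": 49, "weight_kg": 70, "height_m": 1.69,
                   "brSBP_mmHg": 122, "HR_bpm": 66, "cfPWV_mps": 7}
        assert model.predict(subject) == pytest.approx(75.81, abs=0.01)

    def test_all_zero_covariates_no_intercept(self):
        model = SVRegressionResults.from_coefficients(PAPER_COEFFS)
        z = {v: 0.0 for v in PAPER_COEFFS}
        assert model.predict(z) == 0.0

    def test_unit_cfpwv_sensitivity(self):
        model = SVRegressionResults.from_coefficients(PAPER_COEFFS)
        s = {"age": 49, "weight_kg": 70, "height_m": 1.69,
             "brSBP_mmHg": 122, "HR_bpm": 66, "cfPWV_mps": 7}
        s2 = dict(s, cfPWV_mps=8)
        assert model.predict(s2) - model.predict(s) == pytest.approx(-4.23,
                                                                     abs=1e-10)

    def test_missing_variable_errors(self):
        model = SVRegressionResults.from_coefficients(PAPER_COEFFS)
        with pytest.raises(ValidationError, match="cfPWV_mps"):
            model.predict({"age": 49, "weight_kg": 70, "height_m": 1.69,
                           "brSBP_mmHg": 122, "HR_bpm": 66})


class TestCrossValidation:
    def test_1cv_split_sizes(self, linear_cohort):
        cv = cross_validate(linear_cohort, "1cv", seed=0)
        assert cv.fold_sizes == [44]
        assert cv.predictions.notna().sum() == 44

    def test_10cv_fold_sizes_on_144(self, linear_cohort):
        cv = cross_validate(linear_cohort, "10cv", seed=0)
        assert sorted(cv.fold_sizes) == [14] * 6 + [15] * 4
        # every subject is tested exactly once
        assert cv.predictions.notna().all()

    def test_seed_determinism(self, linear_cohort):
        cv1 = cross_validate(linear_cohort, "10cv", seed=12)
        cv2 = cross_validate(linear_cohort, "10cv", seed=12)
        assert cv1.fold_sizes == cv2.fold_sizes
        assert np.allclose(cv1.predictions, cv2.predictions)
        assert cv1.pooled.rmse == cv2.pooled.rmse

    def test_unknown_scheme_rejected(self, linear_cohort):
        with pytest.raises(ValidationError, match="scheme"):
            cross_validate(linear_cohort, "5cv", seed=0)
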