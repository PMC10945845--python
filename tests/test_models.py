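"""Spline basis, mixed-model engine and the three fitted models."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from vigilread import (
    ModelSpec,
    SplineBasis,
    fit_detection_model,
    fit_recall_model,
    fit_time_model,
    linear_bspline_design,
    predict_curve,
    simulate_records_glmm,
)
from vigilread.glmm import fit_nested_glmm
from vigilread.models import design_matrix


class TestSplineBasis:
    def test_partition_of_unity(self):
        basis = SplineBasis()
        pos = np.r_[2.0, 19.9, 20.0, 33.0, 40.0, 199.0, 200.0]
        B = linear_bspline_design(pos, basis)
        assert B.shape == (7, 4)
        assert np.allclose(B.sum(axis=1), 1.0)

    def test_hat_functions_at_knots(self):
        basis = SplineBasis()
        B = linear_bspline_design([20.0, 40.0], basis)
        assert B[0, 1] == pytest.approx(1.0)
        assert B[0, 0] == pytest.approx(0.0) and B[0, 2] == pytest.approx(0.0)
        assert B[1, 2] == pytest.approx(1.0)

    def test_recovers_piecewise_linear_exactly(self, rng):
        """Least squares on noiseless data with kinks at the knots."""
        basis = SplineBasis()
        pos = rng.integers(2, 201, size=500).astype(float)

        def kinked(p):
            return 1.0 - 0.05 * np.minimum(p, 20) - 0.01 * np.clip(p - 20, 0, 20) - 0.002 * np.clip(p - 40, 0, None)

        B = linear_bspline_design(pos, basis)
        coef, *_ = np.linalg.lstsq(B, kinked(pos), rcond=None)
        grid = np.linspace(2, 200, 397)
        fitted = linear_bspline_design(grid, basis) @ coef
        assert np.allclose(fitted, kinked(grid), atol=1e-8)

    def test_out_of_boundary_rejected(self):
        with pytest.raises(ValueError, match="boundary"):
            linear_bspline_design([1.0], SplineBasis())
        with pytest.raises(ValueError, match="inside"):
            SplineBasis(interior_knots=(1.0, 40.0))

    def test_spec_constraints(self):
        with pytest.raises(ValueError, match="linear"):
            ModelSpec("cancer_detected", "binomial", "spline")
        with pytest.raises(ValueError, match="gamma"):
            ModelSpec("reading_time", "binomial", "spline")


RECALL_COEFS = dict(
    intercept=-3.0, spline_1=-0.3, spline_2=-0.45, spline_3=-0.6, age_c=0.01, first_screen=0.1
)
TIME_COEFS = dict(
    intercept=4.3, spline_1=-0.08, spline_2=-0.16, spline_3=-0.29, age_c=0.002, first_screen=0.05
)


@pytest.fixture(scope="module")
def binomial_records():
    df, truth = simulate_records_glmm(
        60_000, RECALL_COEFS, "binomial", n_readers=20, n_centers=5,
        sigma_reader=0.2, sigma_center=0.1, seed=21,
    )
    return df.assign(decision=np.where(df["y"] == 1, "recall", "no_recall")), truth


class TestGLMMEngine:
    def test_zero_variance_matches_pooled_glm(self, binomial_records):
        df, _ = binomial_records
        X, names = design_matrix(df, SplineBasis())
        fit = fit_nested_glmm(
            X, df["y"].to_numpy(), df["reader_id"], df["center_id"],
            "binomial", names, fixed_sigmas=(0.0, 0.0),
        )
        oracle = sm.GLM(df["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.coef - oracle.params)) < 1e-4
        assert np.max(np.abs(fit.se - oracle.bse)) < 1e-4

    def test_zero_variance_matches_pooled_gamma_glm(self):
        df, _ = simulate_records_glmm(
            30_000, TIME_COEFS, "gamma", n_readers=20, n_centers=5,
            sigma_reader=0.15, sigma_center=0.05, gamma_shape=0.8, seed=5,
        )
        X, names = design_matrix(df, SplineBasis())
        fit = fit_nested_glmm(
            X, df["y"].to_numpy(), df["reader_id"], df["center_id"],
            "gamma", names, fixed_sigmas=(0.0, 0.0),
        )
        oracle = sm.GLM(
            df["y"].to_numpy(), X, family=sm.families.Gamma(sm.families.links.Log())
        ).fit()
        assert np.max(np.abs(fit.coef - oracle.params)) < 1e-4

    def test_estimating_variances_never_lowers_likelihood(self, binomial_records):
        df, _ = binomial_records
        X, names = design_matrix(df, SplineBasis())
        y = df["y"].to_numpy()
        pinned = fit_nested_glmm(X, y, df["reader_id"], df["center_id"], "binomial", names, fixed_sigmas=(0.0, 0.0))
        free = fit_nested_glmm(X, y, df["reader_id"], df["center_id"], "binomial", names)
        assert free.log_likelihood >= pinned.log_likelihood - 1e-6

    def test_recovers_generating_coefficients(self, binomial_records):
        df, truth = binomial_records
        fit = fit_recall_model(df)
        for name, est, se in zip(fit.names, fit.glmm.coef, fit.glmm.se):
            assert est == pytest.approx(truth[name], abs=4 * se)
        assert np.sqrt(fit.variance_components["reader"]) == pytest.approx(0.2, abs=0.08)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_agrees_with_lme4_glmer(self, tmp_path, binomial_records):
        """Laplace fit matches lme4's glmer (nAGQ=1) on the same data."""
        df, _ = binomial_records
        X, names = design_matrix(df, SplineBasis())
        out = pd.DataFrame(X, columns=names)
        out["y"] = df["y"].to_numpy()
        out["reader"] = df["reader_id"].to_numpy()
        out["center"] = df["center_id"].to_numpy()
        csv = tmp_path / "records.csv"
        out.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            f <- glmer(y ~ 0 + intercept + spline_1 + spline_2 + spline_3 +
                       age_c + first_screen + (1|center/reader),
                       data = d, family = binomial, nAGQ = 1)
            vc <- as.data.frame(VarCorr(f))
            write.csv(data.frame(coef = fixef(f), se = coef(summary(f))[, 2]),
                      "{tmp_path / 'fixef.csv'}")
            write.csv(data.frame(sd = sqrt(vc$vcov)), "{tmp_path / 'vc.csv'}")
            """
        )
        res = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=600
        )
        assert res.returncode == 0, res.stderr
        r_fix = pd.read_csv(tmp_path / "fixef.csv", index_col=0)
        r_vc = pd.read_csv(tmp_path / "vc.csv", index_col=0)["sd"].to_numpy()
        fit = fit_nested_glmm(
            X, df["y"].to_numpy(), df["reader_id"], df["center_id"], "binomial", names
        )
        assert np.max(np.abs(fit.coef - r_fix["coef"].to_numpy())) < 0.02
        assert np.max(np.abs(fit.se - r_fix["se"].to_numpy())) < 0.02
        ours = np.sort([np.sqrt(v) for v in fit.variance_components.values()])
        assert np.max(np.abs(ours - np.sort(r_vc))) < 0.03


class TestDetectionModel:
    def test_or_per_5_arithmetic(self):
        assert np.exp(5 * -0.0004) == pytest.approx(0.998, abs=1e-4)

    def test_or_transform_consistency(self):
        df, _ = simulate_records_glmm(
            40_000,
            dict(intercept=-4.8, position=0.0, age_c=0.02, first_screen=-0.1),
            "binomial", n_readers=20, n_centers=5, sigma_reader=0.15,
            sigma_center=0.05, position_term="linear", seed=13,
        )
        df = df.assign(
            decision=np.where(df["y"] == 1, "recall", "no_recall"),
            cancer_status=np.where(df["y"] == 1, "screen_detectable", "none"),
        )
        fit = fit_detection_model(df)
        beta = fit.glmm.coef[fit.names.index("position")]
        assert fit.glmm.extra["or_per_5_cases"] == pytest.approx(np.exp(beta) ** 5, rel=1e-10)
        lo, hi = fit.glmm.extra["or_per_5_cases_ci"]
        assert lo <= fit.glmm.extra["or_per_5_cases"] <= hi


class TestTimeModel:
    def test_declining_log_mean_recovered(self):
        df, _ = simulate_records_glmm(
            50_000, TIME_COEFS, "gamma", n_readers=20, n_centers=5,
            sigma_reader=0.1, sigma_center=0.05, gamma_shape=0.8, seed=31,
        )
        df = df.assign(reading_time_seconds=df["y"])
        fit = fit_time_model(df)
        curve = predict_curve(fit, [2, 200])
        assert curve["fitted"].iloc[1] < curve["fitted"].iloc[0]
        assert fit.glmm.extra["gamma_shape"] == pytest.approx(0.8, abs=0.1)

    def test_nonpositive_times_rejected(self):
        df = pd.DataFrame(
            {
                "position": [2, 3], "age": [59.0, 60.0], "first_screen": [False, True],
                "reader_id": [0, 1], "center_id": [0, 1], "reading_time_seconds": [30.0, 0.0],
            }
        )
        with pytest.raises(ValueError, match="exclusions"):
            fit_time_model(df)


@pytest.fixture(scope="module")
def recall_fit(binomial_records):
    df, _ = binomial_records
    return fit_recall_model(df)


class TestPredictCurve:
    def test_curve_is_continuous_piecewise_linear(self, recall_fit):
        grid = np.arange(2.0, 200.01, 0.5)
        curve = predict_curve(recall_fit, grid)
        eta = np.log(curve["fitted"] / (1 - curve["fitted"]))
        # linear predictor has no jumps: second differences vanish except at knots
        d2 = np.abs(np.diff(eta, 2))
        assert np.max(np.diff(curve["fitted"].to_numpy(), 1)) < 0.05  # no jumps
        knot_idx = [int((k - 2.0) / 0.5) for k in (20.0, 40.0)]
        interior = np.ones(len(d2), dtype=bool)
        for k in knot_idx:
            interior[k - 1 : k + 1] = False
        assert np.max(d2[interior]) < 1e-10

    def test_monotone_coefficients_give_monotone_curve(self, recall_fit):
        curve = predict_curve(recall_fit, np.arange(2, 201))
        # generated with monotone declining spline coefficients
        assert curve["fitted"].iloc[0] > curve["fitted"].iloc[-1]
        assert (curve["ci_low"] <= curve["fitted"]).all()
        assert (curve["fitted"] <= curve["ci_high"]).all()

    def test_band_width_grows_where_data_thin(self, recall_fit):
        curve = predict_curve(recall_fit, [20.0, 150.0])
        width = (curve["ci_high"] - curve["ci_low"]) / curve["fitted"]
        assert width.iloc[1] > width.iloc[0]

    def test_out_of_range_rejected(self, recall_fit):
        with pytest.raises(ValueError, match="outside the fitted range"):
            predict_curve(recall_fit, [500.0])


def test_null_position_effect_rarely_significant():
    """With no true position effect the joint Wald test on the spline
    coefficients should be non-significant at 5% in most replicates."""
    from scipy.stats import chi2

    flat = dict(intercept=-3.0, spline_1=0.0, spline_2=0.0, spline_3=0.0, age_c=0.01, first_screen=0.1)
    nonsig = 0
    for seed in range(5):
        df, _ = simulate_records_glmm(
            30_000, flat, "binomial", n_readers=20, n_centers=5,
            sigma_reader=0.2, sigma_center=0.1, seed=100 + seed,
        )
        df = df.assign(decision=np.where(df["y"] == 1, "recall", "no_recall"))
        fit = fit_recall_model(df)
        idx = [fit.names.index(f"spline_{j}") for j in (1, 2, 3)]
        b = fit.glmm.coef[idx]
        V = fit.glmm.cov[np.ix_(idx, idx)]
        stat = float(b @ np.linalg.solve(V, b))
        if chi2.sf(stat, 3) > 0.05:
            nonsig += 1
    assert nonsig >= 3
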