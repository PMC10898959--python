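"""Joint multi-pollutant models, segment odds ratios, diagnostics, curves."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import airmasld as am
from airmasld.link_basis import LinkKind, LinkSpec, rcs_basis
from airmasld.multipollutant import (
    categorized_or_table,
    cohort_fingerprint,
    collinearity_diagnostics,
    compare_models,
    fit_all_linear,
    fit_categorized,
    fit_multipollutant,
    fit_subset,
    pearson_correlations,
    predicted_curve,
    segment_or,
)

LIN_TRUTH = {"pm25": 0.02, "pm10": -0.008, "co": 0.0005,
             "o3": 0.01, "so2": 0.0, "no2": 0.008}


def _linear_cohort(seed, n=20_000, truth=LIN_TRUTH):
    rng = np.random.default_rng(seed)
    X = am.draw_window_means(rng, n)
    eta = -0.5 + sum(t * (X[p] - X[p].mean()) for p, t in truth.items())
    y = (rng.random(n) < expit(eta)).astype(int)
    return X.assign(masld=y)


def _nonlinear_cohort(seed, n=30_000):
    rng = np.random.default_rng(seed)
    X = am.draw_window_means(rng, n)
    eta = (
        -0.8
        + 0.06 * np.maximum(0, X["pm25"] - 34.64)
        + 0.015 * (X["no2"] - 37.5)
    )
    y = (rng.random(n) < expit(eta)).astype(int)
    return X.assign(masld=y)


@pytest.fixture(scope="module")
def nonlinear_model():
    cohort = _nonlinear_cohort(3)
    specs = {
        "pm25": LinkSpec("pm25", LinkKind.THRESHOLD, cutpoint=34.64),
        "pm10": LinkSpec("pm10", LinkKind.INTERACTION, cutpoint=57.93),
        "no2": LinkSpec("no2", LinkKind.RCS,
                        knots=am.default_knots(cohort["no2"].to_numpy(), 4)),
    }
    return cohort, fit_multipollutant(cohort, specs)


class TestJointFit:
    def test_aic_identity(self, nonlinear_model):
        _, m = nonlinear_model
        assert m.aic == pytest.approx(2 * m.n_params - 2 * m.llf, abs=1e-8)

    def test_linear_truth_coefficients_recovered(self):
        cohort = _linear_cohort(0, n=50_000)
        m = fit_all_linear(cohort, pollutants=list(LIN_TRUTH))
        for p, t in LIN_TRUTH.items():
            se = np.sqrt(m.cov_params.loc[p, p])
            assert abs(m.params[p] - t) < 4 * se

    def test_all_linear_equals_generic_fit_with_linear_specs(self):
        cohort = _linear_cohort(1, n=10_000)
        specs = {p: LinkSpec(p, LinkKind.LINEAR) for p in LIN_TRUTH}
        m1 = fit_all_linear(cohort, pollutants=list(LIN_TRUTH))
        m2 = fit_multipollutant(cohort, specs)
        assert m1.llf == pytest.approx(m2.llf, abs=1e-8)
        assert m1.aic == pytest.approx(m2.aic, abs=1e-8)

    def test_per_unit_aor_is_exp_coefficient(self):
        cohort = _linear_cohort(2, n=10_000)
        m = fit_all_linear(cohort, pollutants=list(LIN_TRUTH))
        res = segment_or(m, "pm25", (20.0, 40.0))
        assert res["aor"] == pytest.approx(np.exp(m.params["pm25"]))

    def test_subset_drops_design_columns(self):
        cohort = _nonlinear_cohort(4, n=10_000)
        specs = {
            "pm25": LinkSpec("pm25", LinkKind.THRESHOLD, cutpoint=34.64),
            "pm10": LinkSpec("pm10", LinkKind.INTERACTION, cutpoint=57.93),
            "no2": LinkSpec("no2", LinkKind.LINEAR),
        }
        full = fit_multipollutant(cohort, specs)
        sub = fit_subset(cohort, specs, exclude=["pm10"])
        assert full.n_params - sub.n_params == 3  # interaction block width

    def test_single_pollutant_subset_equals_one_pollutant_model(self):
        cohort = _nonlinear_cohort(5, n=10_000)
        specs = {
            "pm25": LinkSpec("pm25", LinkKind.THRESHOLD, cutpoint=34.64),
            "no2": LinkSpec("no2", LinkKind.LINEAR),
        }
        sub = fit_subset(cohort, specs, exclude=["no2"])
        one = am.fit_candidate(cohort, "pm25", specs["pm25"])
        assert sub.llf == pytest.approx(one.llf, abs=1e-6)

    def test_true_nonlinear_model_beats_all_linear(self):
        wins = 0
        for s in range(10):
            cohort = _nonlinear_cohort(100 + s, n=20_000)
            specs = {
                "pm25": LinkSpec("pm25", LinkKind.THRESHOLD, cutpoint=34.64),
                "no2": LinkSpec("no2", LinkKind.LINEAR),
            }
            best = fit_multipollutant(cohort, specs, with_diagnostics=False)
            lin = fit_all_linear(cohort, pollutants=["pm25", "no2"])
            wins += best.aic < lin.aic
        assert wins >= 9


class TestSegmentOr:
    def test_threshold_below_cutpoint_is_structural_unity(self, nonlinear_model):
        cohort, m = nonlinear_model
        res = segment_or(m, "pm25", (float(cohort["pm25"].min()), 34.64))
        assert res == pytest.approx(
            {**res, "aor": 1.0, "ci_low": 1.0, "ci_high": 1.0}
        )
        assert res["structural"]

    def test_threshold_above_cutpoint(self, nonlinear_model):
        cohort, m = nonlinear_model
        res = segment_or(m, "pm25", (34.64, float(cohort["pm25"].max())))
        b = m.params["pm25_hinge"]
        assert res["aor"] == pytest.approx(np.exp(b))
        assert res["ci_low"] < res["aor"] < res["ci_high"]

    def test_interaction_segment_slopes(self, nonlinear_model):
        cohort, m = nonlinear_model
        below = segment_or(m, "pm10", (30.0, 57.93))
        above = segment_or(m, "pm10", (57.93, 90.0))
        assert below["aor"] == pytest.approx(np.exp(m.params["pm10"]))
        assert above["aor"] == pytest.approx(
            np.exp(m.params["pm10"] + m.params["pm10_x_above"])
        )

    def test_rcs_average_derivative_matches_finite_difference_oracle(
        self, nonlinear_model
    ):
        """Observed-exposure-weighted mean derivative vs central differences
        of the fitted logit."""
        cohort, m = nonlinear_model
        spec = m.specs["no2"]
        beta = m.params[m.column_blocks["no2"]].to_numpy()
        lo, hi = 33.0, 48.0
        res = segment_or(m, "no2", (lo, hi))
        x = cohort["no2"].to_numpy()
        pts = x[(x >= lo) & (x < hi)]
        h = 1e-5
        num = (
            rcs_basis(pts + h, spec.knots) @ beta
            - rcs_basis(pts - h, spec.knots) @ beta
        ) / (2 * h)
        assert np.log(res["aor"]) == pytest.approx(num.mean(), abs=1e-6)

    def test_segment_outside_support_errors(self, nonlinear_model):
        _, m = nonlinear_model
        with pytest.raises(ValueError):
            segment_or(m, "pm25", (500.0, 600.0))


class TestCategorized:
    def test_reference_segment_fixed_at_one(self):
        cohort = _nonlinear_cohort(6, n=15_000)
        m = fit_categorized(cohort, {"pm25": [34.64], "no2": [33.0, 48.0]})
        t = categorized_or_table(m)
        refs = t[t["reference"]]
        assert (refs["aor"] == 1.0).all()
        assert len(t[t["pollutant"] == "no2"]) == 3

    def test_null_pollutant_ci_covers_one(self):
        cover = 0
        for s in range(20):
            rng = np.random.default_rng(300 + s)
            X = am.draw_window_means(rng, 10_000)
            y = (rng.random(10_000) < 0.4).astype(int)  # so2 has no effect
            m = fit_categorized(X.assign(masld=y), {"so2": [10.0]})
            t = categorized_or_table(m)
            row = t[(t["pollutant"] == "so2") & (~t["reference"])].iloc[0]
            cover += row["ci_low"] <= 1.0 <= row["ci_high"]
        assert cover >= 17

    def test_smooth_truth_categorized_fits_worse(self):
        wins = 0
        for s in range(5):
            cohort = _linear_cohort(400 + s, n=20_000)
            lin = fit_all_linear(cohort, pollutants=list(LIN_TRUTH))
            cat = fit_categorized(
                cohort, {p: [float(cohort[p].median())] for p in LIN_TRUTH}
            )
            wins += cat.aic >= lin.aic
        assert wins >= 4

    def test_empty_segment_errors(self):
        cohort = _linear_cohort(7, n=2_000)
        with pytest.raises(ValueError):
            fit_categorized(cohort, {"pm25": [10_000.0]})


class TestDiagnostics:
    def test_orthogonal_columns_unit_vif(self):
        rng = np.random.default_rng(4)
        M = rng.normal(size=(40, 3))
        Q, _ = np.linalg.qr(M - M.mean(axis=0))  # zero-mean orthogonal columns
        d = collinearity_diagnostics(pd.DataFrame(Q, columns=list("abc")))
        assert np.allclose(d["vif"], 1.0, atol=1e-10)

    def test_duplicated_column_infinite_vif(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=50)})
        d = collinearity_diagnostics(X)
        assert np.isinf(d.loc["a", "vif"])
        assert d.loc["a", "tolerance"] == 0.0

    def test_vif_matches_direct_r2_regressions(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        X["d"] = 0.8 * X["a"] + 0.2 * X["d"]
        d = collinearity_diagnostics(X)
        import statsmodels.api as sm

        for col in X.columns:
            others = sm.add_constant(X.drop(columns=col))
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert d.loc[col, "vif"] == pytest.approx(1.0 / (1.0 - r2), abs=1e-10)
            assert d.loc[col, "vif"] == pytest.approx(
                1.0 / d.loc[col, "tolerance"]
            )

    def test_pearson_fisher_intervals_bracket_r(self):
        rng = np.random.default_rng(2)
        X = am.draw_window_means(rng, 5_000)
        t = pearson_correlations(X)
        assert ((t["ci_low"] <= t["r"]) & (t["r"] <= t["ci_high"])).all()


class TestPredictedCurve:
    def test_linear_pollutant_gives_straight_line(self):
        cohort = _linear_cohort(8, n=10_000)
        m = fit_all_linear(cohort, pollutants=list(LIN_TRUTH))
        c = predicted_curve(m, "pm25", n_points=50)
        slopes = np.diff(c.logit) / np.diff(c.grid)
        np.testing.assert_allclose(slopes, m.params["pm25"], atol=1e-10)

    def test_curve_equals_direct_prediction_at_mean_row(self, nonlinear_model):
        cohort, m = nonlinear_model
        grid = np.array([30.0, 40.0, 50.0])
        c = predicted_curve(m, "pm25", grid=grid)
        # direct evaluation: synthetic row with every design column at its mean
        from airmasld.link_basis import basis_matrix

        row = m.design_means.copy()
        for g, got in zip(grid, c.logit):
            vals = row.copy()
            vals["const"] = 1.0
            B = basis_matrix(np.array([g]), m.specs["pm25"])[0]
            for name, v in zip(m.column_blocks["pm25"], B):
                vals[name] = v
            expected = float(vals[m.params.index] @ m.params)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_threshold_curve_flat_below_cutpoint(self, nonlinear_model):
        _, m = nonlinear_model
        grid = np.linspace(20, 34.0, 20)
        c = predicted_curve(m, "pm25", grid=grid)
        assert np.ptp(c.logit) < 1e-12

    def test_grid_outside_range_errors(self, nonlinear_model):
        _, m = nonlinear_model
        with pytest.raises(ValueError):
            predicted_curve(m, "pm25", grid=np.array([-50.0, 1000.0]))

    def test_invariant_to_dummy_recoding(self):
        """Re-coding a binary covariate's reference level shifts coefficients
        but not the predicted curve."""
        cohort = _linear_cohort(9, n=10_000)
        rng = np.random.default_rng(99)
        z = (rng.random(len(cohort)) < 0.4).astype(float)
        cov_a = pd.DataFrame({"z": z})
        cov_b = pd.DataFrame({"z": 1.0 - z})
        pollutants = list(LIN_TRUTH)
        ma = fit_all_linear(cohort, covariates=cov_a, pollutants=pollutants)
        mb = fit_all_linear(cohort, covariates=cov_b, pollutants=pollutants)
        ca = predicted_curve(ma, "pm25", n_points=20)
        cb = predicted_curve(mb, "pm25", n_points=20)
        np.testing.assert_allclose(ca.logit, cb.logit, atol=1e-8)


class TestCompareModels:
    def test_identical_model_zero_delta(self, nonlinear_model):
        _, m = nonlinear_model
        t = compare_models({"a": m, "b": m})
        assert (t["delta_aic"] == 0).all()

    def test_ordering_invariant_to_input_order(self):
        cohort = _nonlinear_cohort(10, n=10_000)
        specs = {"pm25": LinkSpec("pm25", LinkKind.THRESHOLD, cutpoint=34.64)}
        m1 = fit_multipollutant(cohort, specs, with_diagnostics=False)
        m2 = fit_all_linear(cohort, pollutants=["pm25"])
        t1 = compare_models({"best": m1, "lin": m2})
        t2 = compare_models({"lin": m2, "best": m1})
        assert t1["model"].tolist() == t2["model"].tolist()

    def test_mismatched_cohorts_refused(self):
        c1, c2 = _linear_cohort(11, n=2_000), _linear_cohort(12, n=2_000)
        m1 = fit_all_linear(c1, pollutants=["pm25"])
        m2 = fit_all_linear(c2, pollutants=["pm25"])
        with pytest.raises(ValueError):
            compare_models({"a": m1, "b": m2})

    def test_fingerprint_sensitive_to_outcome(self):
        c = _linear_cohort(13, n=1_000)
        f1 = cohort_fingerprint(c)
        c2 = c.copy()
        c2.loc[0, "masld"] = 1 - c2.loc[0, "masld"]
        assert f1 != cohort_fingerprint(c2)
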