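"""Unit and property tests for the spline basis and the additive fit."""

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from sensorgamm.errors import DegenerateCovariateError
from sensorgamm.smooth import (
    _ncs_eval_matrix,
    _ncs_penalty,
    build_smooth_basis,
    evaluate_partial_effects,
    fit_penalized_gam,
    stepwise_select_gam,
)

from .conftest import make_dataset


# --------------------------------------------------------------------------
# basis construction

class TestBasis:
    def test_shape_and_psd(self, rng):
        x = rng.uniform(0, 1, 100)
        b = build_smooth_basis(x, max_df=6)
        assert b.design.shape == (100, 6)
        assert np.allclose(b.design.sum(axis=0), 0.0, atol=1e-9)
        eig = np.linalg.eigvalsh(b.penalty)
        assert eig.min() > -1e-8 * max(eig.max(), 1.0)

    def test_penalty_null_space_is_linear(self, rng):
        # the centered straight line must carry zero penalty
        x = rng.uniform(-3, 5, 200)
        b = build_smooth_basis(x, max_df=6)
        # represent the centered linear function exactly in the basis
        target = x - x.mean()
        coef, res, *_ = np.linalg.lstsq(b.design, target, rcond=None)
        assert np.abs(b.design @ coef - target).max() < 1e-8
        assert coef @ b.penalty @ coef < 1e-10 * (coef @ coef + 1)

    def test_matches_scipy_natural_spline(self, rng):
        knots = np.sort(rng.uniform(0, 10, 7))
        g = rng.standard_normal(7)
        x = np.linspace(knots[0], knots[-1], 97)
        M = _ncs_eval_matrix(x, knots)
        cs = CubicSpline(knots, g, bc_type="natural")
        np.testing.assert_allclose(M @ g, cs(x), atol=1e-10)

    def test_linear_extrapolation_beyond_knots(self, rng):
        # natural spline: linear outside the boundary knots, continuous in
        # value and slope at the boundary
        knots = np.sort(rng.uniform(0, 10, 7))
        g = rng.standard_normal(7)
        cs = CubicSpline(knots, g, bc_type="natural")
        for side, x0 in ((-1.0, knots[0]), (1.0, knots[-1])):
            xs = x0 + side * np.array([0.5, 1.0, 2.0])
            M = _ncs_eval_matrix(xs, knots)
            expected = cs(x0) + (xs - x0) * cs(x0, 1)
            np.testing.assert_allclose(M @ g, expected, atol=1e-10)

    def test_penalty_equals_numeric_curvature_integral(self, rng):
        knots = np.sort(rng.uniform(0, 4, 7))
        g = rng.standard_normal(7)
        S = _ncs_penalty(knots)
        cs = CubicSpline(knots, g, bc_type="natural")
        xx = np.linspace(knots[0], knots[-1], 100001)
        numeric = np.trapezoid(cs(xx, 2) ** 2, xx)
        assert g @ S @ g == pytest.approx(numeric, rel=1e-6)

    def test_constant_covariate_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            build_smooth_basis(np.full(50, 3.0))

    def test_too_few_distinct_values_rejected(self):
        x = np.tile(np.arange(7.0), 10)  # 7 distinct < max_df + 2
        with pytest.raises(DegenerateCovariateError):
            build_smooth_basis(x, max_df=6)


# --------------------------------------------------------------------------
# penalized fit

class TestPenalizedFit:
    def test_exact_linear_response(self, rng):
        n = 500
        x = rng.uniform(0, 10, n)
        y = 2.0 + 0.5 * x
        ds = make_dataset({"x": x}, y)
        fit = fit_penalized_gam(ds, ["x"])
        assert fit.deviance_explained == pytest.approx(100.0, abs=1e-6)
        departure = fit.fitted - y
        assert np.abs(departure).max() < 1e-6 * (y.max() - y.min())

    def test_sine_recovery(self, rng):
        n = 2000
        x = rng.uniform(0, 1, n)
        truth = np.sin(2 * np.pi * x)
        y = truth + rng.normal(scale=0.1, size=n)
        ds = make_dataset({"x": x}, y)
        fit = fit_penalized_gam(ds, ["x"])
        est = fit.terms["x"].basis.design @ fit.terms["x"].coefficients
        centered = truth - truth.mean()
        rmse = np.sqrt(np.mean((est - centered) ** 2))
        assert rmse <= 0.05  # 5% of unit amplitude

    def test_intercept_only(self, rng):
        y = rng.normal(size=100)
        ds = make_dataset({"x": rng.normal(size=100)}, y)
        fit = fit_penalized_gam(ds, [])
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(fit.fitted, y.mean())
        assert fit.edf_total == pytest.approx(1.0)

    def test_linear_limit_matches_ols(self, rng):
        n = 400
        x1 = rng.uniform(0, 1, n)
        x2 = rng.normal(size=n)
        y = 1.0 + 2.0 * x1 - 0.7 * x2 + rng.normal(scale=0.3, size=n)
        ds = make_dataset({"x1": x1, "x2": x2}, y)
        fit = fit_penalized_gam(ds, ["x1", "x2"],
                                lambdas={"x1": 1e9, "x2": 1e9})
        X = np.column_stack([np.ones(n), x1, x2])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rel = np.abs(fit.fitted - X @ beta).max() / np.abs(X @ beta).max()
        assert rel < 1e-6
        assert fit.edf_total == pytest.approx(3.0, abs=1e-4)

    def test_edf_trace_identity(self, rng):
        # blockwise edf must equal the trace of the full influence matrix
        n = 300
        x1 = rng.uniform(0, 1, n)
        x2 = rng.uniform(-1, 1, n)
        y = np.sin(6 * x1) + x2 ** 2 + rng.normal(scale=0.2, size=n)
        ds = make_dataset({"x1": x1, "x2": x2}, y)
        fit = fit_penalized_gam(ds, ["x1", "x2"])
        # rebuild the influence matrix explicitly
        b1, b2 = fit.terms["x1"].basis, fit.terms["x2"].basis
        X = np.hstack([np.ones((n, 1)), b1.design, b2.design])
        A = X.T @ X
        A[1:7, 1:7] += fit.terms["x1"].lam * b1.penalty
        A[7:13, 7:13] += fit.terms["x2"].lam * b2.penalty
        H = X @ np.linalg.solve(A, X.T)
        assert fit.edf_total == pytest.approx(np.trace(H), abs=1e-6)
        assert fit.edf_total == pytest.approx(
            1.0 + sum(t.edf for t in fit.terms.values()), abs=1e-6)

    def test_rss_nonincreasing_in_decreasing_lambda(self, rng):
        n = 400
        x = rng.uniform(0, 1, n)
        y = np.sin(4 * np.pi * x) + rng.normal(scale=0.3, size=n)
        ds = make_dataset({"x": x}, y)
        rss = [fit_penalized_gam(ds, ["x"], lambdas={"x": lam}).rss
               for lam in (1e6, 1e3, 1.0, 1e-3, 1e-6)]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_fitted_invariant_to_affine_rescaling(self, rng):
        n = 600
        x = rng.uniform(0, 1, n)
        y = np.sin(2 * np.pi * x) + rng.normal(scale=0.1, size=n)
        f1 = fit_penalized_gam(make_dataset({"x": x}, y), ["x"])
        f2 = fit_penalized_gam(make_dataset({"x": 100.0 * x - 42.0}, y), ["x"])
        np.testing.assert_allclose(f1.fitted, f2.fitted, atol=1e-6)

    def test_edf_cap_six(self, rng):
        # lambda -> 0 cannot push a smooth past max_df
        n = 500
        x = rng.uniform(0, 1, n)
        y = rng.normal(size=n)
        fit = fit_penalized_gam(make_dataset({"x": x}, y), ["x"],
                                lambdas={"x": 1e-12})
        assert fit.terms["x"].edf <= 6.0 + 1e-8

    def test_adding_covariate_does_not_reduce_deviance(self, rng):
        n = 800
        x1 = rng.uniform(0, 1, n)
        x2 = rng.normal(size=n)
        y = np.sin(2 * np.pi * x1) + rng.normal(scale=0.3, size=n)
        ds = make_dataset({"x1": x1, "x2": x2}, y)
        small = fit_penalized_gam(ds, ["x1"])
        large = fit_penalized_gam(ds, ["x1", "x2"])
        assert large.deviance_explained >= small.deviance_explained - 1e-6


# --------------------------------------------------------------------------
# stepwise selection

class TestStepwise:
    def test_single_strong_candidate_selected(self, rng):
        n = 800
        x = rng.uniform(0, 1, n)
        y = 3.0 * np.sin(2 * np.pi * x) + rng.normal(scale=0.3, size=n)
        ds = make_dataset({"x": x}, y)
        fit = stepwise_select_gam(ds, ["x"])
        assert fit.term_names == ["x"]
        null_aic = fit_penalized_gam(ds, [], rows=fit.rows).aic
        assert fit.aic < null_aic

    def test_support_recovery_single_seed(self, rng):
        n = 3000
        x = {f"x{i}": rng.uniform(0, 1, n) for i in range(6)}
        y = (np.sin(2 * np.pi * x["x0"]) + (x["x1"] - 0.5) ** 2 * 4
             + np.tanh(3 * (x["x2"] - 0.5)) + rng.normal(scale=0.3, size=n))
        ds = make_dataset(x, y)
        fit = stepwise_select_gam(ds, list(x))
        assert {"x0", "x1", "x2"}.issubset(set(fit.term_names))

    def test_trace_records_aic_descent(self, rng):
        n = 500
        x1 = rng.uniform(0, 1, n)
        x2 = rng.normal(size=n)
        y = 2 * x1 + rng.normal(scale=0.2, size=n)
        fit = stepwise_select_gam(make_dataset({"x1": x1, "x2": x2}, y),
                                  ["x1", "x2"])
        aics = [a for _, a in fit.trace]
        assert all(a > b for a, b in zip(aics, aics[1:]))


# --------------------------------------------------------------------------
# partial effects

class TestPartialEffects:
    def _linear_fit(self, rng, n=400):
        x = rng.uniform(0, 10, n)
        y = 1.0 + 0.8 * x + rng.normal(scale=0.05, size=n)
        ds = make_dataset({"x": x}, y)
        return x, fit_penalized_gam(ds, ["x"])

    def test_linear_truth_line_through_mean(self, rng):
        x, fit = self._linear_fit(rng)
        table = evaluate_partial_effects(fit, grid_points=50)
        vals = table["value"].to_numpy()
        eff = table["effect"].to_numpy()
        slope = np.polyfit(vals, eff, 1)[0]
        assert slope == pytest.approx(0.8, rel=0.02)
        # zero close to the covariate mean
        crossing = vals[np.argmin(np.abs(eff))]
        assert abs(crossing - x.mean()) < (x.max() - x.min()) / 20

    def test_two_grid_points_at_range_ends(self, rng):
        x, fit = self._linear_fit(rng)
        table = evaluate_partial_effects(fit, grid_points=2)
        assert len(table) == 2
        assert table["value"].iloc[0] == pytest.approx(x.min())
        assert table["value"].iloc[1] == pytest.approx(x.max())

    def test_grid_points_below_two_rejected(self, rng):
        _, fit = self._linear_fit(rng)
        with pytest.raises(ValueError):
            evaluate_partial_effects(fit, grid_points=1)

    def test_sine_truth_coverage(self, rng):
        n = 2000
        x = rng.uniform(0, 1, n)
        truth_fn = lambda v: np.sin(2 * np.pi * v)  # noqa: E731
        y = truth_fn(x) + rng.normal(scale=0.1, size=n)
        fit = fit_penalized_gam(make_dataset({"x": x}, y), ["x"])
        table = evaluate_partial_effects(fit, grid_points=100)
        centered = truth_fn(table["value"].to_numpy()) - truth_fn(x).mean()
        inside = np.abs(table["effect"] - centered) <= 2 * table["se"]
        assert inside.mean() >= 0.90
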