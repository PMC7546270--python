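"""Estimation machinery: oracle equivalence, recovery, standard errors, AIC."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from leafedm import (
    ExponentialParams,
    InsufficientDataError,
    ResourceResponseParams,
    ValidationError,
    fit_exponential,
    fit_linear,
    fit_model,
    fit_resource_response,
    hyperbola_form,
    information_criteria,
)
from leafedm.fitting import estimate_standard_errors
from leafedm.synthetic_data import NoiseSpec, derive_seed, gen_enzyme_series, gen_nitrogen_series

from conftest import make_enzyme_series, make_nitrogen_series


def exponential_grid_oracle(x, y, alpha_range, b_range, n=201):
    """Brute-force 2-D grid search over (alpha, b), independent of the NLS path."""
    alphas = np.linspace(*alpha_range, n)
    bs = np.linspace(*b_range, n)
    best = (np.inf, None, None)
    for a in alphas:
        resid = a * np.exp(np.outer(bs, x)) - y
        rss = (resid**2).sum(axis=1)
        i = int(np.argmin(rss))
        if rss[i] < best[0]:
            best = (float(rss[i]), float(a), float(bs[i]))
    return best


class TestFitExponential:
    def test_zero_noise_recovery(self):
        series = gen_enzyme_series(
            ExponentialParams(2.0, 0.5), x_grid=[0, 1, 2, 3, 4], noise=NoiseSpec(level=0.0)
        )
        fit = fit_exponential(series)
        assert fit.converged
        assert fit.params.alpha == pytest.approx(2.0, abs=1e-6)
        assert fit.params.b == pytest.approx(0.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_matches_grid_oracle_on_toy_series(self, toy_exp_series):
        """The NLS optimum beats/meets a dense brute-force (alpha, b) grid."""
        fit = fit_exponential(toy_exp_series)
        rss_grid, a_grid, b_grid = exponential_grid_oracle(
            toy_exp_series.x, toy_exp_series.y, (1.0, 4.0), (0.2, 0.8), n=241
        )
        assert fit.rss <= rss_grid + 1e-9
        # and lies within two grid cells of the grid optimum (the discrete
        # argmin can slide along the correlated (alpha, b) valley)
        assert abs(fit.params.alpha - a_grid) <= 2 * (4.0 - 1.0) / 240
        assert abs(fit.params.b - b_grid) <= 2 * (0.8 - 0.2) / 240

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential(make_enzyme_series([1, 2], [1, 2]))

    def test_warns_on_leaf_n_predictor(self):
        series = make_nitrogen_series([1, 2, 3, 4], [2, 4, 8, 16])
        with pytest.warns(UserWarning, match="predictor_kind"):
            fit_exponential(series)

    def test_deterministic_under_seed(self):
        series = gen_enzyme_series(
            ExponentialParams(15.0, 0.02),
            x_grid=np.linspace(10, 100, 12),
            noise=NoiseSpec(level=0.08, seed=5),
        )
        a = fit_exponential(series, seed=3)
        b = fit_exponential(series, seed=3)
        assert a.params == b.params
        assert a.rss == b.rss


class TestFitLinear:
    def test_exact_line(self):
        fit = fit_linear(make_enzyme_series([0, 1, 2, 3], [1, 3, 5, 7]))
        assert fit.params.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.params.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.converged

    def test_constant_response(self):
        fit = fit_linear(make_enzyme_series([0, 1, 2, 3], [4, 4, 4, 4]))
        assert fit.params.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == 0.0

    def test_matches_normal_equations_oracle(self, toy_exp_series):
        """Closed-form normal-equation solution computed by hand formulas."""
        x, y = toy_exp_series.x, toy_exp_series.y
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        fit = fit_linear(toy_exp_series)
        assert fit.params.slope == pytest.approx(slope, rel=1e-12)
        assert fit.params.intercept == pytest.approx(intercept, rel=1e-12)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValidationError, match="rank"):
            fit_linear(make_enzyme_series([2, 2, 2], [1, 2, 3]))


def nitrogen_oracle(x, z, reduced):
    """Coarse 3/4-D grid plus Nelder-Mead refinement, independent of least_squares."""
    xmin, xrange = x.min(), np.ptp(x)
    best = (np.inf, None)
    a_grid = np.linspace(0.5, 8.0, 10)
    k_grid = np.geomspace(0.05 * xrange, 10 * xrange, 10)
    r0_grid = np.linspace(xmin - xrange, xmin - 1e-6, 8)
    c_grid = [0.0] if reduced else np.linspace(-2, 2, 7)
    for a in a_grid:
        for k in k_grid:
            for r0 in r0_grid:
                s = x - r0
                u = s / (k + s)
                for c in c_grid:
                    rss = float(np.sum((a * u + c - z) ** 2))
                    if rss < best[0]:
                        best = (rss, [a, k, r0] + ([] if reduced else [c]))

    def objective(theta):
        a, k, r0 = theta[0], theta[1], theta[2]
        c = 0.0 if reduced else theta[3]
        if a <= 0 or k <= 0 or r0 > xmin - 1e-12:
            return 1e12
        s = x - r0
        return float(np.sum((a * s / (k + s) + c - z) ** 2))

    res = minimize(objective, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return min(best[0], float(res.fun))


class TestFitResourceResponse:
    def test_zero_noise_recovery_reduced(self):
        truth = ResourceResponseParams(ln_P_max=4.72, Kp=29.19, reduced=True)
        series = gen_nitrogen_series(truth, noise=NoiseSpec(kind="additive_gaussian", level=0.0))
        fit = fit_resource_response(series, reduced=True)
        assert fit.converged
        assert fit.params.ln_P_max == pytest.approx(4.72, abs=1e-4)
        assert fit.params.Kp == pytest.approx(29.19, abs=1e-4)
        assert abs(fit.params.R0) < 1e-4

    def test_zero_noise_full_recovers_identifiable_combinations(self):
        """The free-baseline variant recovers (D, B, m); raw parameters sit on a ridge."""
        truth = ResourceResponseParams(ln_P_max=4.0, Kp=20.0, R0=5.0, ln_P0=1.0)
        series = gen_nitrogen_series(
            truth,
            R_grid=np.linspace(6.0, 120.0, 12),
            noise=NoiseSpec(kind="additive_gaussian", level=0.0),
        )
        fit = fit_resource_response(series, reduced=False)
        assert fit.converged
        assert fit.rss < 1e-12
        want, got = hyperbola_form(truth), hyperbola_form(fit.params)
        for key in ("D", "B", "m"):
            assert got[key] == pytest.approx(want[key], rel=1e-4), key

    def test_matches_grid_refinement_oracle(self, toy_nitrogen_series):
        z = np.log(toy_nitrogen_series.y)
        for reduced in (True, False):
            fit = fit_resource_response(toy_nitrogen_series, reduced=reduced)
            rss_oracle = nitrogen_oracle(toy_nitrogen_series.x, z, reduced)
            assert fit.rss <= rss_oracle + 1e-6

    def test_offset_bound_respected(self, toy_nitrogen_series):
        for reduced in (True, False):
            fit = fit_resource_response(toy_nitrogen_series, reduced=reduced)
            assert fit.params.R0 <= toy_nitrogen_series.x.min()

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_resource_response(make_nitrogen_series([1, 2, 3], [1, 2, 3]), reduced=False)

    def test_warns_on_enzyme_predictor(self):
        series = make_enzyme_series([1, 5, 10, 20, 40], [2, 6, 9, 11, 12])
        with pytest.warns(UserWarning, match="predictor_kind"):
            fit_resource_response(series, reduced=True)


class TestStandardErrors:
    def test_linear_matches_textbook_formula(self, toy_exp_series):
        x, y = toy_exp_series.x, toy_exp_series.y
        fit = fit_linear(toy_exp_series)
        n = len(x)
        resid = y - (fit.params.intercept + fit.params.slope * x)
        s2 = np.sum(resid**2) / (n - 2)
        sxx = np.sum((x - x.mean()) ** 2)
        se_slope = math.sqrt(s2 / sxx)
        se_intercept = math.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
        assert fit.se[0] == pytest.approx(se_intercept, rel=1e-10)
        assert fit.se[1] == pytest.approx(se_slope, rel=1e-10)

    def test_exponential_se_matches_monte_carlo_sd(self):
        """Linearized SEs within 20% of the empirical SD over 1000 replicates."""
        truth = ExponentialParams(alpha=17.0, b=0.02)
        grid = np.linspace(10.0, 100.0, 20)
        estimates, ses = [], []
        for rep in range(1000):
            series = gen_enzyme_series(
                truth, x_grid=grid, noise=NoiseSpec(level=0.05, seed=derive_seed(99, rep))
            )
            fit = fit_exponential(series, seed=1)
            estimates.append([fit.params.alpha, fit.params.b])
            ses.append(fit.se)
        sd = np.std(np.array(estimates), axis=0, ddof=1)
        mean_se = np.mean(np.array(ses), axis=0)
        np.testing.assert_allclose(mean_se, sd, rtol=0.20)

    def test_zero_degrees_of_freedom_flagged(self):
        """n equal to the free-parameter count leaves no residual variance."""
        series = make_nitrogen_series([2.0, 2.0, 20.0], [3.0, 4.0, 30.0])
        fit = fit_resource_response(series, reduced=True)
        assert not fit.se_defined
        assert np.all(np.isnan(fit.se))
        assert "degrees of freedom" in fit.message

    def test_ridge_degeneracy_reported_not_zeroed(self):
        """Non-identifiable full variant: SEs undefined, never silently zero."""
        truth = ResourceResponseParams(ln_P_max=4.0, Kp=20.0, R0=0.0, ln_P0=0.5)
        series = gen_nitrogen_series(
            truth, noise=NoiseSpec(kind="additive_gaussian", level=0.03, seed=2)
        )
        fit = fit_resource_response(series, reduced=False)
        assert not fit.se_defined
        assert np.all(np.isnan(fit.se))

    def test_requires_converged_fit(self, toy_exp_series):
        fit = fit_exponential(toy_exp_series)
        fit.converged = False
        with pytest.raises(ValidationError):
            estimate_standard_errors(fit, toy_exp_series)


class TestInformationCriteria:
    def test_one_extra_parameter_costs_two(self):
        aic1, _ = information_criteria(5.0, 30, 3)
        aic2, _ = information_criteria(5.0, 30, 4)
        assert aic2 - aic1 == pytest.approx(2.0, abs=1e-12)

    def test_frozen_hand_evaluation(self):
        aic, aicc = information_criteria(10.0, 20, 3)
        assert aic == pytest.approx(-7.862943611198906, abs=1e-12)
        assert aicc == pytest.approx(-6.362943611198906, abs=1e-12)

    def test_halving_rss_drops_aic_by_n_ln2(self):
        n = 37
        aic_full, _ = information_criteria(8.0, n, 4)
        aic_half, _ = information_criteria(4.0, n, 4)
        assert aic_full - aic_half == pytest.approx(n * math.log(2.0), abs=1e-10)

    def test_aicc_exceeds_aic_and_converges(self):
        aic, aicc = information_criteria(3.0, 12, 4)
        assert aicc > aic
        aic_big, aicc_big = information_criteria(3.0, 100000, 4)
        assert aicc_big - aic_big == pytest.approx(0.0, abs=1e-3)

    def test_aicc_undefined_for_tiny_n(self):
        aic, aicc = information_criteria(3.0, 5, 4)
        assert np.isfinite(aic)
        assert np.isnan(aicc)

    def test_exact_fit_limit_and_invalid_input(self):
        aic, _ = information_criteria(0.0, 10, 3)
        assert aic == -np.inf
        with pytest.raises(ValidationError):
            information_criteria(-1.0, 10, 3)


class TestFitDispatchAndNoiseMonotonicity:
    def test_unknown_kind_rejected(self, toy_exp_series):
        with pytest.raises(ValidationError, match="unknown model kind"):
            fit_model(toy_exp_series, "quadratic")

    def test_error_grows_with_noise(self):
        """Median |error| of b and Kp is nondecreasing in noise level (200 reps each)."""
        levels = [0.0, 0.02, 0.05, 0.10]
        exp_truth = ExponentialParams(alpha=17.0, b=0.02)
        exp_grid = np.linspace(10, 100, 15)
        nit_truth = ResourceResponseParams(ln_P_max=4.7, Kp=30.0, reduced=True)
        nit_grid = np.linspace(3.0, 120.0, 15)
        med_b, med_kp = [], []
        for level in levels:
            err_b, err_kp = [], []
            for rep in range(200):
                s = gen_enzyme_series(
                    exp_truth,
                    x_grid=exp_grid,
                    noise=NoiseSpec(level=level, seed=derive_seed(1234, rep)),
                )
                err_b.append(abs(fit_exponential(s, seed=1).params.b - exp_truth.b))
                sn = gen_nitrogen_series(
                    nit_truth,
                    R_grid=nit_grid,
                    noise=NoiseSpec(
                        kind="additive_gaussian", level=level, seed=derive_seed(4321, rep)
                    ),
                )
                err_kp.append(
                    abs(fit_resource_response(sn, reduced=True, seed=1).params.Kp - nit_truth.Kp)
                )
            med_b.append(np.median(err_b))
            med_kp.append(np.median(err_kp))
        assert all(np.diff(med_b) >= 0)
        assert all(np.diff(med_kp) >= 0)
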