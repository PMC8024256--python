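"""SUR estimation: OLS stage, covariance estimator, LSUR/NSUR with oracles.

Each estimator is checked against exactly one independent brute-force
oracle: the linear system against a densely assembled stacked GLS solve,
the nonlinear system against a per-equation coarse-grid search polished by
a general-purpose simplex minimizer.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from crmsur.records import SYSTEM_COMPONENTS
from crmsur.sur import (
    SingularCovarianceError,
    SystemData,
    equation_diagnostics,
    estimate_sigma,
    fit_lsur,
    fit_nsur,
    fit_ols_equation,
    foliage_slope_screen,
    nsur_start_values,
    significance_stars,
)
from conftest import make_system


def design(x):
    return np.column_stack([np.ones(len(x)), x])


class TestOlsEquation:
    def test_exact_fit_has_zero_rse(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_ols_equation(0.5 + 0.25 * x, design(x), "stem")
        assert fit.rse == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_constant_response(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_ols_equation(np.full(4, 0.7), design(x), "stem")
        assert fit.params.beta1 == pytest.approx(0.0, abs=1e-12)
        assert fit.params.beta0 == pytest.approx(0.7, abs=1e-12)

    def test_four_point_normal_equations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 3.0])
        fit = fit_ols_equation(y, design(x), "stem")
        assert fit.params.beta0 == pytest.approx(0.5, abs=1e-12)
        assert fit.params.beta1 == pytest.approx(0.6, abs=1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(0)
        x = rng.uniform(3, 20, size=30)
        y = 0.6 - 0.02 * x + rng.normal(0, 0.05, size=30)
        fit = fit_ols_equation(y, design(x), "stem")
        res = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.params.beta0 == pytest.approx(res.params[0], rel=1e-9)
        assert fit.params.beta1 == pytest.approx(res.params[1], rel=1e-9)
        assert fit.se_beta0 == pytest.approx(res.bse[0], rel=1e-9)
        assert fit.p_beta1 == pytest.approx(res.pvalues[1], rel=1e-6)
        assert fit.rse == pytest.approx(np.sqrt(res.mse_resid), rel=1e-9)

    def test_rank_deficiency_errors(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(np.linalg.LinAlgError):
            fit_ols_equation(np.arange(5.0), X, "stem")


class TestEstimateSigma:
    def test_identical_residuals_have_unit_correlation(self):
        e = np.random.default_rng(1).normal(size=10)
        E = np.column_stack([e, e, 2 * e])
        sigma = estimate_sigma(E)
        sd = np.sqrt(np.diag(sigma))
        corr = sigma / np.outer(sd, sd)
        assert np.allclose(np.abs(corr), 1.0, atol=1e-12)

    def test_orthogonal_residuals_uncorrelated(self):
        E = np.column_stack(
            [[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0], [1.0, 1.0, -1.0, -1.0]]
        )
        sigma = estimate_sigma(E)
        assert sigma[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert sigma[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_n_policy(self):
        E = np.column_stack([[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        sigma = estimate_sigma(E, policy="n")
        assert sigma[0, 1] == pytest.approx(-2.0 / 3.0, abs=1e-12)
        corr01 = sigma[0, 1] / np.sqrt(sigma[0, 0] * sigma[1, 1])
        assert corr01 == pytest.approx(-1.0, abs=1e-12)

    def test_df_policy_divisors(self):
        E = np.random.default_rng(2).normal(size=(12, 3))
        geo = estimate_sigma(E, ks=(2, 2, 2), policy="geometric")
        plain = estimate_sigma(E, policy="n")
        assert np.allclose(geo * 10, plain * 12)

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError):
            estimate_sigma(np.zeros((2, 3)), ks=(2, 2, 2))

    @settings(max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(4, 30))
    def test_always_symmetric_psd(self, seed, n):
        E = np.random.default_rng(seed).normal(size=(n, 3))
        sigma = estimate_sigma(E)
        assert np.allclose(sigma, sigma.T)
        assert np.linalg.eigvalsh(sigma)[0] >= -1e-12


class TestLsur:
    def test_identity_weight_equals_per_equation_ols(self, linear_system):
        fit = fit_lsur(linear_system, sigma_override=np.eye(3))
        X = design(linear_system.x)
        for j, c in enumerate(SYSTEM_COMPONENTS):
            ols = fit_ols_equation(linear_system.y[:, j], X, c)
            assert fit.fits[c].params.beta0 == pytest.approx(ols.params.beta0, abs=1e-10)
            assert fit.fits[c].params.beta1 == pytest.approx(ols.params.beta1, abs=1e-10)

    def test_kruskal_equivalence_with_shared_design(self, linear_system):
        """FGLS equals OLS when every equation shares the same regressors."""
        fit = fit_lsur(linear_system)
        X = design(linear_system.x)
        for j, c in enumerate(SYSTEM_COMPONENTS):
            ols = fit_ols_equation(linear_system.y[:, j], X, c)
            assert fit.fits[c].params.beta0 == pytest.approx(ols.params.beta0, abs=1e-8)
            assert fit.fits[c].params.beta1 == pytest.approx(ols.params.beta1, abs=1e-8)

    def test_matches_dense_stacked_gls_oracle(self, linear_system):
        """Coefficients solve the densely assembled stacked GLS system."""
        fit = fit_lsur(linear_system)
        X = design(linear_system.x)
        n = linear_system.n
        Z = np.kron(np.eye(3), X)
        omega_inv = np.kron(np.linalg.inv(fit.sigma), np.eye(n))
        ystack = linear_system.y.T.reshape(-1)
        beta = np.linalg.solve(Z.T @ omega_inv @ Z, Z.T @ omega_inv @ ystack)
        got = np.concatenate(
            [[fit.fits[c].params.beta0, fit.fits[c].params.beta1]
             for c in SYSTEM_COMPONENTS]
        )
        assert np.allclose(got, beta, atol=1e-8)

    def test_one_step_mode_runs_single_iteration(self, linear_system):
        fit = fit_lsur(linear_system, iterate=False)
        assert fit.converged
        assert fit.n_iter == 1

    def test_singular_covariance_raises(self):
        x = np.linspace(3, 20, 8)
        rng = np.random.default_rng(3)
        y1 = np.clip(0.5 - 0.01 * x + rng.normal(0, 0.02, 8), 0, 1)
        y2 = np.clip(y1 - 0.1, 0, 1)  # identical residuals to y1
        y3 = np.clip(0.2 + 0.005 * x + rng.normal(0, 0.02, 8), 0, 1)
        data = SystemData(x=x, y=np.column_stack([y1, y2, y3]))
        with pytest.raises(SingularCovarianceError):
            fit_lsur(data)

    def test_moderate_sample_recovery(self):
        """Coefficients approach the generating values as n grows."""
        data = make_system(n=400, seed=8)
        fit = fit_lsur(data)
        from crmsur.synthetic import SyntheticConfig

        truth = SyntheticConfig().true_beta
        for c in SYSTEM_COMPONENTS:
            assert fit.fits[c].params.beta0 == pytest.approx(truth[c][0], abs=0.02)
            assert fit.fits[c].params.beta1 == pytest.approx(truth[c][1], abs=0.002)

    def test_correlation_matrix_well_formed(self, linear_system):
        fit = fit_lsur(linear_system)
        assert np.allclose(np.diag(fit.corr), 1.0)
        assert np.all(np.abs(fit.corr) <= 1 + 1e-12)
        sd = np.sqrt(np.diag(fit.sigma))
        assert np.allclose(fit.corr * np.outer(sd, sd), fit.sigma, atol=1e-12)


class TestNsurStartValues:
    def test_exact_recovery_from_noiseless_data(self):
        x = np.array([5.0, 10.0, 15.0, 20.0])
        y = np.column_stack(
            [
                np.exp(1.0 - 2.0 / x) / 3,  # scaled into [0, 1]
                np.full(4, np.exp(-0.5)),
                np.exp(-0.5 + 3.0 / x) / 5,
            ]
        )
        data = SystemData(x=x, y=y)
        start = nsur_start_values(data)
        assert start["stem"].beta0 == pytest.approx(1.0 - np.log(3), abs=1e-10)
        assert start["stem"].beta1 == pytest.approx(-2.0, abs=1e-10)
        assert start["branch"].beta0 == pytest.approx(-0.5, abs=1e-10)
        assert start["branch"].beta1 == pytest.approx(0.0, abs=1e-10)
        assert start["twig"].beta1 == pytest.approx(3.0, abs=1e-10)

    def test_requires_positive_responses(self):
        data = SystemData(
            x=np.array([5.0, 10.0, 15.0]),
            y=np.array([[0.5, 0.3, 0.0], [0.5, 0.3, 0.1], [0.5, 0.3, 0.1]]),
        )
        with pytest.raises(ValueError, match="positive"):
            nsur_start_values(data)


def _nsur_truth():
    return {"stem": (-0.4, -2.0), "branch": (-1.2, 1.5), "twig": (-2.2, -1.0)}


def _nsur_data(n=12, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    x = np.linspace(4.0, 19.0, n)
    truth = _nsur_truth()
    y = np.column_stack(
        [np.exp(b0 + b1 / x) for b0, b1 in truth.values()]
    )
    if noise:
        y = np.clip(y + rng.normal(0, noise, size=y.shape), 1e-4, 1.0)
    return SystemData(x=x, y=y)


class TestNsur:
    def test_noiseless_recovery(self):
        fit = fit_nsur(_nsur_data())
        truth = _nsur_truth()
        for c in SYSTEM_COMPONENTS:
            assert fit.fits[c].params.beta0 == pytest.approx(truth[c][0], abs=1e-6)
            assert fit.fits[c].params.beta1 == pytest.approx(truth[c][1], abs=1e-6)
            assert np.allclose(fit.fits[c].residuals, 0.0, atol=1e-8)

    def test_identity_weight_matches_grid_polish_oracle(self):
        """With identity weighting NSUR is per-equation nonlinear least
        squares; a coarse grid search polished by Nelder-Mead must agree."""
        data = _nsur_data(n=12, noise=0.03, seed=42)
        fit = fit_nsur(data, sigma_override=np.eye(3))
        for j, c in enumerate(SYSTEM_COMPONENTS):
            y = data.y[:, j]

            def sse(p):
                return float(np.sum((y - np.exp(p[0] + p[1] / data.x)) ** 2))

            grid0 = np.linspace(-4.0, 1.0, 41)
            grid1 = np.linspace(-4.0, 4.0, 41)
            best = min(
                ((b0, b1) for b0 in grid0 for b1 in grid1), key=lambda p: sse(p)
            )
            polished = minimize(sse, best, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-14,
                                         "maxiter": 5000})
            assert fit.fits[c].params.beta0 == pytest.approx(polished.x[0], abs=1e-4)
            assert fit.fits[c].params.beta1 == pytest.approx(polished.x[1], abs=1e-4)

    def test_objective_non_increasing(self):
        """Within each iteration (fixed weighting) the step never
        increases the generalized criterion; the criterion rescales when
        sigma updates, so monotonicity is per iteration."""
        fit = fit_nsur(_nsur_data(n=30, noise=0.04, seed=7))
        hist = fit.objective_history
        assert len(hist) >= 1
        for before, after in hist:
            assert after <= before + 1e-12 * (1 + abs(before))

    def test_convergence_flag_reported(self):
        fit = fit_nsur(_nsur_data(n=30, noise=0.04, seed=7))
        assert fit.converged
        capped = fit_nsur(_nsur_data(n=30, noise=0.04, seed=7), max_iter=1)
        assert not capped.converged  # reported, never raised


class TestDiagnostics:
    @pytest.mark.parametrize(
        "p, stars",
        [
            (0.2, "ns"),
            (0.03, "*"),
            (0.05, "*"),
            (0.0005, "***"),
            (0.001, "***"),
            (1e-5, "****"),
            (0.0001, "****"),
            (0.01, "**"),
        ],
    )
    def test_star_scheme(self, p, stars):
        assert significance_stars(p) == stars

    def test_equation_diagnostics_report(self, linear_system):
        fit = fit_lsur(linear_system)
        rep = equation_diagnostics(fit.fits["stem"], linear_system.n)
        assert rep["component"] == "stem"
        assert rep["stars_beta1"] == significance_stars(rep["p_beta1"])
        assert rep["rse"] > 0

    def test_foliage_screen_not_significant_at_truth(self, ratios_12):
        """The foliage complement carries no detectable dbh trend at study
        scale, supporting its exclusion from the fitted system."""
        screen = foliage_slope_screen(ratios_12, "dbh")
        assert screen["p_beta1"] > 0.05
        assert not screen["significant"]
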