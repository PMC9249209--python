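"""Estimation machinery: quadrature vs oracle, limits, LMM cross-checks."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

import steppedwedge as sw
from steppedwedge.glmm import (
    DesignMatrices, _agq_q1, _laplace_q1, cluster_marglik_oracle,
    natural_cubic_spline_basis, wald_ci,
)


def _random_instance(rng, n_clusters=None, rows=None, sigma=None):
    C = n_clusters or int(rng.integers(2, 6))
    m = rows or int(rng.integers(5, 50))
    n = C * m
    ci = np.repeat(np.arange(C), m)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = rng.normal(0, 1, 2)
    s = sigma if sigma is not None else float(rng.uniform(0.05, 2.0))
    u = rng.normal(0, s, C)
    y = (rng.random(n) < expit(X @ beta + u[ci])).astype(float)
    return X, y, ci, C, beta, s


class TestQuadrature:
    def test_agq_matches_bruteforce_oracle(self):
        """AGQ(25) marginal log-likelihood agrees with adaptive numerical
        integration to 1e-6 on randomised small instances."""
        rng = np.random.default_rng(2024)
        for _ in range(12):
            X, y, ci, C, beta, s = _random_instance(rng)
            params = np.append(beta, s)
            ll_agq, _ = _agq_q1(params, X, y, np.ones(len(y)), ci, C, 25)
            ll_oracle = sum(
                cluster_marglik_oracle(X[ci == c], y[ci == c], beta, s)
                for c in range(C)
            )
            assert abs(ll_agq - ll_oracle) < 1e-6

    def test_laplace_close_to_agq_on_well_conditioned_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(6):
            X, y, ci, C, beta, s = _random_instance(rng, rows=40, sigma=0.3)
            params = np.append(beta, s)
            ll_lap, _ = _laplace_q1(params, X, y, np.ones(len(y)), ci, C)[:2]
            ll_agq, _ = _agq_q1(params, X, y, np.ones(len(y)), ci, C, 25)
            assert abs(ll_lap - ll_agq) < 1e-2

    def test_oracle_sigma_zero_is_plain_bernoulli(self):
        rng = np.random.default_rng(3)
        X, y, ci, C, beta, _ = _random_instance(rng, n_clusters=2, rows=10)
        ll = cluster_marglik_oracle(X, y, beta, 0.0)
        eta = X @ beta
        assert np.isclose(ll, np.sum(y * eta - np.logaddexp(0, eta)), atol=1e-12)

    def test_oracle_symmetric_in_random_effect_sign(self):
        # all-zero beta and symmetric outcomes: flipping y flips eta's role
        X = np.ones((6, 1))
        y = np.array([1, 0, 1, 0, 1, 0], dtype=float)
        ll = cluster_marglik_oracle(X, y, np.zeros(1), 0.8)
        ll_flip = cluster_marglik_oracle(X, 1 - y, np.zeros(1), 0.8)
        assert np.isclose(ll, ll_flip, atol=1e-10)

    def test_laplace_gradient_matches_numeric(self):
        rng = np.random.default_rng(11)
        X, y, ci, C, beta, s = _random_instance(rng, n_clusters=4, rows=30)
        w = np.ones(len(y))
        params = np.append(beta, s)
        _, _, g = _laplace_q1(params, X, y, w, ci, C, want_grad=True)
        num = np.zeros_like(params)
        for k in range(len(params)):
            e = np.zeros_like(params); e[k] = 1e-6
            num[k] = (_laplace_q1(params + e, X, y, w, ci, C)[0]
                      - _laplace_q1(params - e, X, y, w, ci, C)[0]) / 2e-6
        assert np.allclose(g, num, atol=1e-6)


class TestGlmmFits:
    def _dm(self, X, y, ci, names=None, weights=None):
        return DesignMatrices(
            X=X, columns=names or [f"x{k}" for k in range(X.shape[1])], y=y,
            cluster_index=ci, cluster_labels=sorted(set(ci)), weights=weights,
        )

    def test_sigma_zero_limit_matches_plain_logistic(self):
        rng = np.random.default_rng(23)
        n, C = 3000, 7
        ci = rng.integers(0, C, n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)])
        y = (rng.random(n) < expit(X @ np.array([-2.0, 0.5, 0.3]))).astype(float)
        fit = sw.fit_logistic_glmm(self._dm(X, y, ci), method="laplace")
        ref = sm.Logit(y, X).fit(disp=0)
        assert fit.boundary
        assert np.max(np.abs(fit.beta.to_numpy() - ref.params)) < 1e-4
        assert np.max(np.abs(fit.se.to_numpy() - ref.bse)) < 1e-4

    def test_doubled_weights_scale_se_by_inverse_sqrt2(self):
        """Frequency weights multiply the conditional log-likelihood rows;
        with no cluster variance, doubling every weight leaves the point
        estimates untouched and scales the SEs by exactly 1/sqrt(2)."""
        rng = np.random.default_rng(24)
        n, C = 1500, 5
        ci = rng.integers(0, C, n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = (rng.random(n) < expit(X @ np.array([-1.5, 0.6]))).astype(float)
        f1 = sw.fit_logistic_glmm(self._dm(X, y, ci), method="laplace")
        f2 = sw.fit_logistic_glmm(self._dm(X, y, ci, weights=np.full(n, 2.0)),
                                  method="laplace")
        assert f1.boundary and f2.boundary
        assert np.allclose(f1.beta, f2.beta, atol=1e-5)
        assert np.allclose(f2.se / f1.se, 1 / np.sqrt(2), atol=1e-4)

    def test_parameter_recovery_glmm(self):
        """Single large draw: the AGQ fit recovers the generating log-OR
        within Wald error."""
        rng = np.random.default_rng(23)
        n, C = 30000, 7
        ci = rng.integers(0, C, n)
        z = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), z])
        true = np.array([-5.0, np.log(2)])
        y = (rng.random(n) < expit(X @ true)).astype(float)
        fit = sw.fit_logistic_glmm(
            self._dm(X, y, ci, names=["intercept", "intervention"]), method="agq")
        lo, hi = fit.term_ci("intervention")
        assert lo < np.log(2) < hi

    def test_centring_invariance_of_intervention_or(self):
        rng = np.random.default_rng(24)
        n, C = 4000, 7
        ci = rng.integers(0, C, n)
        t = rng.uniform(-1, 1, n)
        z = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), z, t])
        y = (rng.random(n) < expit(-3 + 0.5 * z + 0.2 * t)).astype(float)
        names = ["intercept", "intervention", "time"]
        f1 = sw.fit_logistic_glmm(self._dm(X, y, ci, names), method="laplace")
        X2 = X.copy(); X2[:, 2] += 5.0
        f2 = sw.fit_logistic_glmm(self._dm(X2, y, ci, names), method="laplace")
        assert np.isclose(f1.beta["intervention"], f2.beta["intervention"], atol=1e-5)
        assert not np.isclose(f1.beta["intercept"], f2.beta["intercept"], atol=1e-3)

    def test_random_slope_laplace_runs(self):
        rng = np.random.default_rng(25)
        n, C = 3000, 7
        ci = rng.integers(0, C, n)
        z = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), z])
        slope = rng.normal(0.5, 0.3, C)
        y = (rng.random(n) < expit(-2.5 + slope[ci] * z)).astype(float)
        dm = DesignMatrices(X=X, columns=["intercept", "intervention"], y=y,
                            cluster_index=ci, cluster_labels=list(range(C)),
                            Z_spec="intercept+intervention")
        fit = sw.fit_logistic_glmm(dm, method="laplace")
        assert fit.converged
        assert set(fit.random_effect_sd) == {"intercept", "intervention"}
        lo, hi = fit.term_ci("intervention")
        assert lo < 0.5 < hi


class TestLmm:
    def test_matches_statsmodels_mixedlm(self):
        rng = np.random.default_rng(31)
        n, C = 2500, 7
        ci = rng.integers(0, C, n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n), rng.normal(size=n)])
        u = rng.normal(0, 0.3, C)
        y = X @ np.array([2.2, -0.25, 0.1]) + u[ci] + rng.normal(0, 0.9, n)
        dm = DesignMatrices(X=X, columns=["intercept", "intervention", "x"], y=y,
                            cluster_index=ci, cluster_labels=list(range(C)))
        fit = sw.fit_lmm(dm)
        ref = sm.MixedLM(y, X, groups=ci).fit(reml=True)
        assert np.max(np.abs(fit.beta.to_numpy() - ref.fe_params)) < 1e-6
        assert np.max(np.abs(fit.se.to_numpy() - ref.bse_fe)) < 1e-3
        assert np.isclose(fit.random_effect_sd["intercept"],
                          float(np.sqrt(np.asarray(ref.cov_re)[0, 0])), atol=1e-3)
        assert np.isclose(fit.random_effect_sd["residual"],
                          float(np.sqrt(ref.scale)), atol=1e-4)

    def test_sigma_zero_matches_ols(self):
        rng = np.random.default_rng(32)
        n, C = 2000, 7
        ci = rng.integers(0, C, n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        y = X @ np.array([2.0, -0.3]) + rng.normal(0, 1, n)
        dm = DesignMatrices(X=X, columns=["intercept", "intervention"], y=y,
                            cluster_index=ci, cluster_labels=list(range(C)))
        fit = sw.fit_lmm(dm)
        ols = sm.OLS(y, X).fit()
        assert np.max(np.abs(fit.beta.to_numpy() - ols.params)) < 1e-6
        assert fit.boundary

    def test_gmr_parameter_recovery(self, design):
        """LOS simulation truth 0.78 with negligible site variance: the
        fitted geometric mean ratio lands within Monte-Carlo error."""
        df = sw.generate_parametric(design, n=30000, seed=33)
        fit = sw.run_analysis(df, design, "A", outcome="los")
        assert fit.effect["scale"] == "GMR"
        assert fit.effect["ci_low"] < 0.78 < fit.effect["ci_high"]
        assert abs(fit.effect["estimate"] - 0.78) < 0.03

    def test_compound_symmetry_marginal_covariance(self):
        """Within-site covariance of the outcome equals the random-intercept
        variance (compound symmetry)."""
        rng = np.random.default_rng(34)
        n, C = 40000, 8
        ci = rng.integers(0, C, n)
        su, se_ = 0.5, 1.0
        u = rng.normal(0, su, C)
        y = 1.0 + u[ci] + rng.normal(0, se_, n)
        X = np.ones((n, 1))
        dm = DesignMatrices(X=X, columns=["intercept"], y=y,
                            cluster_index=ci, cluster_labels=list(range(C)))
        fit = sw.fit_lmm(dm)
        # empirical within-cluster covariance of distinct members
        means = pd.Series(y).groupby(ci).mean()
        emp_between = float(means.var(ddof=1))
        assert abs(fit.random_effect_sd["intercept"] ** 2 - emp_between) < 0.2
        assert abs(fit.random_effect_sd["residual"] - se_) < 0.05

    def test_null_ci_coverage(self):
        """Null LOS effect: the 95% CI covers 1 in about 95% of replicates."""
        rng = np.random.default_rng(35)
        n, C, reps = 1200, 7, 150
        cover = 0
        for _ in range(reps):
            ci = rng.integers(0, C, n)
            z = rng.integers(0, 2, n).astype(float)
            u = rng.normal(0, 0.2, C)
            y = 2.0 + u[ci] + rng.normal(0, 0.8, n)
            dm = DesignMatrices(X=np.column_stack([np.ones(n), z]),
                                columns=["intercept", "intervention"], y=y,
                                cluster_index=ci, cluster_labels=list(range(C)))
            fit = sw.fit_lmm(dm)
            lo, hi = fit.term_ci("intervention")
            cover += lo < 0 < hi
        frac = cover / reps
        assert abs(frac - 0.95) < 3 * np.sqrt(0.95 * 0.05 / reps)


class TestSplineAndWald:
    def test_basis_dimension(self):
        x = np.linspace(0, 1, 200)
        assert natural_cubic_spline_basis(x, 3).shape == (200, 4)
        assert natural_cubic_spline_basis(x, 1).shape == (200, 2)

    def test_reproduces_linear_functions_exactly(self):
        rng = np.random.default_rng(41)
        x = np.sort(rng.uniform(-2, 3, 300))
        B = np.column_stack([np.ones(len(x)), natural_cubic_spline_basis(x, 3)])
        y = 2.0 * x - 1.0
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        assert np.max(np.abs(B @ coef - y)) < 1e-9

    def test_natural_tails_are_linear(self):
        x = np.linspace(0, 1, 50)
        qs = np.quantile(x, [0.25, 0.5, 0.75])
        grid = np.linspace(1.5, 3.0, 40)  # beyond the upper boundary knot
        B = natural_cubic_spline_basis(grid, 3, knots=qs, boundary=(0.0, 1.0))
        assert np.all(np.isfinite(B))
        second_diff = np.diff(B, n=2, axis=0)
        assert np.max(np.abs(second_diff)) < 1e-8

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            natural_cubic_spline_basis(np.ones(50), 3)

    @pytest.mark.parametrize(
        "coef, se, level, expected",
        [(0.0, 1.0, 0.95, (-1.959964, 1.959964)),
         (1.0, 0.5, 0.95, (0.020018, 1.979982))],
    )
    def test_wald_ci_values(self, coef, se, level, expected):
        lo, hi = wald_ci(coef, se, level)
        assert np.allclose((lo, hi), expected, atol=1e-5)

    def test_wald_ci_geometric_symmetry_and_monotonicity(self):
        lo, hi = wald_ci(0.4, 0.3)
        assert np.isclose(np.exp(lo) * np.exp(hi), np.exp(0.4) ** 2)
        lo90, hi90 = wald_ci(0.4, 0.3, level=0.90)
        assert lo90 > lo and hi90 < hi
        with pytest.raises(ValueError):
            wald_ci(0.0, 0.0)
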