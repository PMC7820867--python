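"""Likelihood machinery: DM pmf, Dirichlet density, regression MLE, LRT."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from cytodm.dirichlet import (
    counts_to_proportions,
    dirichlet_logpdf,
    dm_logpmf,
    fit_dirichlet_regression,
    lrt_pvalue,
)


def _dm_pmf_oracle(counts, alpha):
    """Direct gamma-product evaluation of the DM pmf (no log tricks)."""
    n = sum(counts)
    a = sum(alpha)
    value = math.gamma(n + 1) * math.gamma(a) / math.gamma(n + a)
    for c, al in zip(counts, alpha):
        value *= math.gamma(c + al) / (math.gamma(c + 1) * math.gamma(al))
    return value


class TestDmLogpmf:
    def test_symmetric_two_category(self):
        assert dm_logpmf([1, 0], [1.0, 1.0]) == pytest.approx(np.log(0.5))

    def test_gamma_product_value(self):
        # frozen from the gamma-product oracle: 72/210
        assert dm_logpmf([1, 2], [2.0, 3.0]) == pytest.approx(np.log(72 / 210))

    def test_matches_oracle_on_random_cases(self, rng):
        for _ in range(100):
            J = int(rng.integers(2, 5))
            counts = rng.integers(0, 6, size=J)
            alpha = rng.uniform(0.2, 5.0, size=J)
            expected = _dm_pmf_oracle(counts.tolist(), alpha.tolist())
            assert dm_logpmf(counts, alpha) == pytest.approx(
                np.log(expected), abs=1e-10
            )

    @pytest.mark.parametrize("N,J", [(4, 3), (6, 2), (5, 3)])
    def test_normalization(self, N, J, rng):
        alpha = rng.uniform(0.3, 4.0, size=J)
        total = sum(
            np.exp(dm_logpmf(np.array(c), alpha))
            for c in itertools.product(range(N + 1), repeat=J)
            if sum(c) == N
        )
        assert total == pytest.approx(1.0, abs=1e-10)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 1_000_000))
    def test_permutation_invariance(self, seed):
        r = np.random.default_rng(seed)
        J = int(r.integers(2, 6))
        counts = r.integers(0, 20, size=J)
        alpha = r.uniform(0.1, 10.0, size=J)
        perm = r.permutation(J)
        assert dm_logpmf(counts, alpha) == pytest.approx(
            dm_logpmf(counts[perm], alpha[perm]), abs=1e-12
        )

    def test_multinomial_limit(self, rng):
        """alpha = c*p with huge c approaches the multinomial pmf."""
        from scipy.stats import multinomial

        p = np.array([0.2, 0.3, 0.5])
        counts = np.array([3, 4, 13])
        lm = multinomial.logpmf(counts, counts.sum(), p)
        ld = dm_logpmf(counts, 1e6 * p)
        assert abs(ld - lm) / abs(lm) < 1e-3

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dm_logpmf([1, -1], [1.0, 1.0])
        with pytest.raises(ValueError):
            dm_logpmf([1, 1], [1.0, 0.0])


class TestDirichletLogpdf:
    def test_uniform_density_is_flat(self):
        assert dirichlet_logpdf([0.3, 0.7], [1.0, 1.0]) == pytest.approx(0.0)

    def test_beta22_closed_form(self):
        # Beta(2,2) density at 1/2 is 6 * 0.25 = 1.5
        assert dirichlet_logpdf([0.5, 0.5], [2.0, 2.0]) == pytest.approx(np.log(1.5))

    def test_scipy_agreement(self, rng):
        from scipy.stats import dirichlet as sp_dirichlet

        alpha = rng.uniform(0.5, 4.0, size=4)
        p = rng.dirichlet(alpha)
        assert dirichlet_logpdf(p, alpha) == pytest.approx(
            sp_dirichlet.logpdf(p, alpha), abs=1e-9
        )

    def test_quadrature_normalization(self):
        alpha = np.array([2.3, 1.7])
        x = np.linspace(1e-6, 1 - 1e-6, 20001)
        dens = np.array([np.exp(dirichlet_logpdf([xi, 1 - xi], alpha)) for xi in x])
        assert np.trapezoid(dens, x) == pytest.approx(1.0, abs=1e-6)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            dirichlet_logpdf([0.0, 1.0], [1.0, 1.0])


class TestCountsToProportions:
    def test_pseudocount_formula(self):
        out = counts_to_proportions(np.array([[0, 10]]), 0.5)
        assert np.allclose(out, [[0.5 / 11, 10.5 / 11]])

    def test_rows_sum_to_one(self, rng):
        counts = rng.integers(0, 100, size=(20, 5))
        counts[:, 0] += 1
        out = counts_to_proportions(counts)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-12)
        assert (out > 0).all()

    def test_zero_pseudocount_plain_proportions(self):
        out = counts_to_proportions(np.array([[2, 2, 4]]), 0.0)
        assert np.allclose(out, [[0.25, 0.25, 0.5]])

    def test_zero_total_row(self):
        with pytest.raises(ValueError):
            counts_to_proportions(np.array([[0, 0]]))


class TestDirichletRegression:
    def test_intercept_only_recovery(self):
        rng = np.random.default_rng(7)
        alpha = np.array([2.0, 5.0, 1.0, 8.0])
        P = rng.dirichlet(alpha, size=2000)
        fit = fit_dirichlet_regression(np.ones((2000, 1)), P)
        assert fit.converged
        assert np.allclose(np.exp(fit.coefficients[0]), alpha, rtol=0.05)

    def test_duplication_doubles_loglik(self, rng):
        P = rng.dirichlet([2.0, 3.0, 4.0], size=60)
        x = rng.normal(size=60)
        X = np.column_stack([np.ones(60), x])
        fit = fit_dirichlet_regression(X, P)
        fit2 = fit_dirichlet_regression(np.vstack([X, X]), np.vstack([P, P]))
        assert np.allclose(fit2.coefficients, fit.coefficients, atol=1e-4)
        assert fit2.log_likelihood == pytest.approx(2 * fit.log_likelihood, rel=1e-6)

    def test_full_fit_at_least_null(self, rng):
        P = rng.dirichlet([1.0, 2.0, 3.0], size=50)
        x = rng.normal(size=50)
        full = fit_dirichlet_regression(np.column_stack([np.ones(50), x]), P)
        null = fit_dirichlet_regression(np.ones((50, 1)), P)
        assert full.log_likelihood >= null.log_likelihood - 1e-8

    def test_rmse_decreases_with_n(self):
        """MLE consistency: coefficient error shrinks as n grows."""
        B = np.array([[0.2, 0.8, 1.4], [0.9, 0.0, -0.7]])
        rmses = []
        for n in (100, 400, 1600):
            rng = np.random.default_rng(n)
            x = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            P = np.vstack([rng.dirichlet(np.exp(X[i] @ B)) for i in range(n)])
            fit = fit_dirichlet_regression(X, P)
            rmses.append(float(np.sqrt(((fit.coefficients - B) ** 2).mean())))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_rank_deficient_design(self, rng):
        P = rng.dirichlet([1.0, 1.0], size=30)
        X = np.column_stack([np.ones(30), np.ones(30)])
        with pytest.raises(ValueError, match="rank"):
            fit_dirichlet_regression(X, P)


class TestLrt:
    def test_equal_likelihoods(self, rng):
        P = rng.dirichlet([2.0, 2.0], size=40)
        fit = fit_dirichlet_regression(np.ones((40, 1)), P)
        stat, p = lrt_pvalue(fit, fit, df=2)
        assert stat == 0.0 and p == 1.0

    def test_chi_square_reference(self):
        from cytodm.dirichlet import DirichletRegFit

        null = DirichletRegFit(np.zeros((1, 2)), -10.0, True, 1, 0.0, 50)
        full = DirichletRegFit(np.zeros((2, 2)), -10.0 + 3.84 / 2, True, 1, 0.0, 50)
        stat, p = lrt_pvalue(full, null, df=1)
        assert stat == pytest.approx(3.84)
        assert p == pytest.approx(0.05, abs=0.001)

    def test_null_calibration_small(self):
        """Under an independent covariate the LRT p-values are uniform."""
        pvals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 60
            P = rng.dirichlet([1.5, 2.5, 3.0, 6.0], size=n)
            x = rng.normal(size=n)
            X = np.column_stack([np.ones(n), x])
            full = fit_dirichlet_regression(X, P)
            null = fit_dirichlet_regression(np.ones((n, 1)), P)
            pvals.append(lrt_pvalue(full, null, df=4)[1])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_inverted_nesting_flagged(self):
        from cytodm.dirichlet import DirichletRegFit

        null = DirichletRegFit(np.zeros((1, 2)), -5.0, True, 1, 0.0, 50)
        worse_full = DirichletRegFit(np.zeros((2, 2)), -9.0, True, 1, 0.0, 50)
        with pytest.raises(RuntimeError, match="optimizer"):
            lrt_pvalue(worse_full, null, df=1)
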