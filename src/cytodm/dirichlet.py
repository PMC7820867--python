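"""Dirichlet and Dirichlet-multinomial likelihoods, and maximum-likelihood
Dirichlet regression with likelihood-ratio testing.

Parametrization: the "alternative" (common-reference-free) form, with every
concentration parameter modelled on the log scale,

    alpha_ij = exp(x_i' B_j),   j = 1..J,

so a fitted coefficient matrix B is (p x J) with row 0 the intercepts. The
same link is used by the screening step (Dirichlet density on interior
proportions) and by the Bayesian variable-selection step (Dirichlet-
multinomial on raw counts), which makes coefficients comparable across steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln
from scipy.stats import chi2

__all__ = [
    "dm_logpmf",
    "dirichlet_logpdf",
    "counts_to_proportions",
    "fit_dirichlet_regression",
    "fit_dm_regression",
    "lrt_pvalue",
    "DirichletRegFit",
]


def dm_logpmf(counts: np.ndarray, alpha: np.ndarray) -> float:
    """Log pmf of the Dirichlet-multinomial distribution.

    With N = sum(counts) and A = sum(alpha):

        log P = logG(N+1) - sum_j logG(n_j+1)
              + logG(A) - logG(N+A)
              + sum_j [logG(n_j + a_j) - logG(a_j)]

    Finite for every valid input, including N = 0 (log of 1).
    """
    counts = np.asarray(counts, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if counts.shape != alpha.shape:
        raise ValueError("counts and alpha must have the same length")
    if (counts < 0).any():
        raise ValueError("negative counts")
    if not np.all(alpha > 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be strictly positive and finite")
    n = counts.sum()
    a = alpha.sum()
    return float(
        gammaln(n + 1)
        - gammaln(counts + 1).sum()
        + gammaln(a)
        - gammaln(n + a)
        + (gammaln(counts + alpha) - gammaln(alpha)).sum()
    )


def dirichlet_logpdf(proportions: np.ndarray, alpha: np.ndarray) -> float:
    """Log density of Dirichlet(alpha) at an interior point of the simplex."""
    p = np.asarray(proportions, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if p.shape != alpha.shape:
        raise ValueError("proportions and alpha must have the same length")
    if not np.all(alpha > 0) or not np.all(np.isfinite(alpha)):
        raise ValueError("alpha must be strictly positive and finite")
    if (p <= 0).any() or (p >= 1).any() or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("proportions must lie strictly inside the simplex and sum to 1")
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * np.log(p)).sum()
    )


def counts_to_proportions(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Map count rows to strictly interior compositions.

    (count + pseudocount) / (total + J * pseudocount), rowwise. The default
    pseudocount 0.5 keeps zero counts off the simplex boundary, where the
    Dirichlet density is undefined.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("every row must have a positive total")
    J = counts.shape[1]
    return (counts + pseudocount) / (totals + J * pseudocount)[:, None]


@dataclass
class DirichletRegFit:
    """Result of a maximum-likelihood Dirichlet regression fit.

    ``coefficients`` is (p x J) on the log-concentration scale;
    ``log_likelihood`` is the summed (not mean) Dirichlet log density.
    """

    coefficients: np.ndarray
    log_likelihood: float
    converged: bool
    n_iterations: int
    gradient_norm: float
    n_samples: int


def _dirichlet_reg_negll_grad(
    b_flat: np.ndarray, X: np.ndarray, logP: np.ndarray, p: int, J: int
) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and its gradient w.r.t. the flat (p*J) B."""
    n = X.shape[0]
    B = b_flat.reshape(p, J)
    eta = X @ B
    # overflow guard: the optimizer can wander; clip keeps the line search alive
    alpha = np.exp(np.clip(eta, -30.0, 30.0))
    A = alpha.sum(axis=1)
    ll = (gammaln(A) - gammaln(alpha).sum(axis=1) + ((alpha - 1) * logP).sum(axis=1)).sum()
    dl_dalpha = digamma(A)[:, None] - digamma(alpha) + logP
    grad = X.T @ (alpha * dl_dalpha)
    return -ll / n, -grad.ravel() / n


def fit_dirichlet_regression(
    X: np.ndarray,
    proportions: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> DirichletRegFit:
    """Fit alpha_i = exp(X_i B) by maximum likelihood (L-BFGS, analytic grad).

    Deterministic start: intercepts at the log of the mean composition scaled
    to total concentration 10; all other coefficients 0. ``tol`` is the
    convergence tolerance on the max-abs gradient of the per-sample (mean)
    log-likelihood; the optimizer itself targets ``tol / 100``.
    """
    X = np.asarray(X, dtype=float)
    P = np.atleast_2d(np.asarray(proportions, dtype=float))
    n, p = X.shape
    J = P.shape[1]
    if P.shape[0] != n:
        raise ValueError("X and proportions disagree on the number of samples")
    if n < p * J:
        raise ValueError(f"need at least {p * J} samples for {p * J} parameters, have {n}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    logP = np.log(P)
    if not np.all(np.isfinite(logP)):
        raise ValueError("proportions must be strictly interior (no zeros)")
    B0 = np.zeros((p, J))
    B0[0] = np.log(10.0 * P.mean(axis=0))
    res = minimize(
        _dirichlet_reg_negll_grad,
        B0.ravel(),
        args=(X, logP, p, J),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol / 100, "maxls": 60},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    return DirichletRegFit(
        coefficients=res.x.reshape(p, J),
        log_likelihood=float(-res.fun * n),
        converged=bool(grad_norm < tol),
        n_iterations=int(res.nit),
        gradient_norm=grad_norm,
        n_samples=n,
    )


def _dm_reg_negll_grad(
    b_flat: np.ndarray, X: np.ndarray, Y: np.ndarray, Ntot: np.ndarray, p: int, J: int
) -> tuple[float, np.ndarray]:
    n = X.shape[0]
    B = b_flat.reshape(p, J)
    alpha = np.exp(np.clip(X @ B, -30.0, 30.0))
    A = alpha.sum(axis=1)
    ll = (
        gammaln(A) - gammaln(Ntot + A)
        + (gammaln(Y + alpha) - gammaln(alpha)).sum(axis=1)
    ).sum()
    dl_dalpha = (
        (digamma(A) - digamma(Ntot + A))[:, None]
        + digamma(Y + alpha)
        - digamma(alpha)
    )
    grad = X.T @ (alpha * dl_dalpha)
    return -ll / n, -grad.ravel() / n


def fit_dm_regression(
    X: np.ndarray,
    counts: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> DirichletRegFit:
    """Maximum-likelihood Dirichlet-multinomial regression on raw counts.

    Same log link, start and convergence conventions as
    :func:`fit_dirichlet_regression`, but the response is the count matrix
    itself — no pseudocount needed. Used as the sensitivity path for
    screening when zero-heavy or low-depth tables make the
    proportions-based Dirichlet likelihood questionable. The reported
    log-likelihood omits the count-dependent multinomial normalization
    constant, which cancels in likelihood ratios between nested fits.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(counts, dtype=float))
    n, p = X.shape
    J = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and counts disagree on the number of samples")
    if (Y < 0).any():
        raise ValueError("negative counts")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")
    Ntot = Y.sum(axis=1)
    mean_p = (Y.sum(axis=0) + 0.5) / (Y.sum() + 0.5 * J)
    B0 = np.zeros((p, J))
    B0[0] = np.log(10.0 * mean_p)
    res = minimize(
        _dm_reg_negll_grad,
        B0.ravel(),
        args=(X, Y, Ntot, p, J),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol / 100, "maxls": 60},
    )
    grad_norm = float(np.max(np.abs(res.jac)))
    return DirichletRegFit(
        coefficients=res.x.reshape(p, J),
        log_likelihood=float(-res.fun * n),
        converged=bool(grad_norm < tol),
        n_iterations=int(res.nit),
        gradient_norm=grad_norm,
        n_samples=n,
    )


def lrt_pvalue(
    full: DirichletRegFit, null: DirichletRegFit, df: int
) -> tuple[float, float]:
    """Likelihood-ratio test of nested Dirichlet regression fits.

    Returns ``(statistic, p)`` with statistic = 2 (ll_full - ll_null) clamped
    at 0 and p from the chi-square upper tail on ``df`` degrees of freedom
    (df = J per added covariate).
    """
    if df < 1:
        raise ValueError("df must be a positive integer")
    delta = full.log_likelihood - null.log_likelihood
    # a nested null cannot beat the full fit by more than numerical noise
    if delta < -1e-6 * max(1.0, abs(null.log_likelihood)):
        raise RuntimeError(
            f"full fit log-likelihood {full.log_likelihood:.6f} is below the null's "
            f"{null.log_likelihood:.6f}: optimizer failure"
        )
    stat = max(0.0, 2.0 * delta)
    return stat, float(chi2.sf(stat, df))
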