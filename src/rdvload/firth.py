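"""Firth-penalized logistic regression with profile-likelihood inference.

The burden models here maximize the penalized log-likelihood

    l*(beta) = l(beta) + tau * log det( X' W(beta) X ),   W = diag(pi (1 - pi))

with tau = 1/2 (Firth's bias-reduction penalty; Jeffreys prior mode).
The penalty keeps estimates finite under complete separation, which is
the regime rare-variant carrier collapsing lives in.  Inference follows
the profile penalized likelihood: confidence limits are the coefficient
values where the profile drops by chi2_1(level)/2, and the p-value is a
penalized likelihood-ratio test against beta_j = 0.  Wald statistics
from the inverse Fisher information are also reported.

Setting ``tau=0`` recovers ordinary maximum likelihood, which is used as
an independent cross-check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import chi2


class RankDeficientError(ValueError):
    """Design matrix is not full column rank."""


@dataclass
class FirthFit:
    """Result of a (possibly constrained) penalized logistic fit."""

    beta: np.ndarray
    loglik: float            # penalized log-likelihood at the optimum
    converged: bool
    n_iter: int
    fisher_info: np.ndarray  # X' W X at the optimum
    tau: float = 0.5

    def wald_se(self) -> np.ndarray:
        return np.sqrt(np.diag(np.linalg.inv(self.fisher_info)))


def penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray,
                     tau: float = 0.5) -> float:
    """Evaluate l*(beta) = l(beta) + tau log|X'WX|."""
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    if tau == 0.0:
        return ll
    pi = expit(eta)
    w = pi * (1.0 - pi)
    sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
    if sign <= 0:
        return -np.inf
    return ll + tau * logdet


def _check_rank(X: np.ndarray, names) -> None:
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns via small R diagonal in a pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [str(names[j]) if names is not None else f"col{j}"
               for j in range(p) if diag[j] < 1e-8 * max(diag.max(), 1.0)]
        raise RankDeficientError(
            f"design matrix is rank deficient; collinear columns: {bad or 'unknown'}"
        )


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    tau: float = 0.5,
    fixed: dict[int, float] | None = None,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
    column_names=None,
    check_rank: bool = True,
) -> FirthFit:
    """Maximize the penalized log-likelihood by Newton steps with step-halving.

    Parameters
    ----------
    fixed:
        Coefficients held at given values (used for profile likelihoods
        and the penalized LRT); the penalty is always computed from the
        full design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("need at least one case and one control")
    if check_rank:
        _check_rank(X, column_names)

    fixed = fixed or {}
    free = np.array([j for j in range(p) if j not in fixed], dtype=int)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    for j, v in fixed.items():
        beta[j] = v

    ll = penalized_loglik(X, y, beta, tau)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        pi = expit(eta)
        w = pi * (1.0 - pi)
        xtwx = X.T @ (X * w[:, None])
        if tau > 0.0:
            # hat diagonal h_i = w_i x_i' (X'WX)^{-1} x_i
            sol = np.linalg.solve(xtwx, X.T)
            h = w * np.einsum("ij,ji->i", X, sol)
            resid = y - pi + 2.0 * tau * h * (0.5 - pi)
        else:
            resid = y - pi
        score = X.T @ resid
        if np.max(np.abs(score[free])) < tol if free.size else True:
            converged = True
            break
        delta = np.zeros(p)
        delta[free] = np.linalg.solve(xtwx[np.ix_(free, free)], score[free])
        # step-halving on the penalized objective
        step = 1.0
        for _ in range(25):
            cand = beta + step * delta
            ll_new = penalized_loglik(X, y, cand, tau)
            if ll_new > ll - 1e-12:
                break
            step *= 0.5
        else:
            cand, ll_new = beta, ll
        beta, ll = cand, ll_new

    eta = X @ beta
    w = expit(eta) * (1.0 - expit(eta))
    return FirthFit(
        beta=beta,
        loglik=penalized_loglik(X, y, beta, tau),
        converged=converged,
        n_iter=it,
        fisher_info=X.T @ (X * w[:, None]),
        tau=tau,
    )


def profile_loglik(X, y, j: int, value: float, tau: float = 0.5,
                   beta0=None) -> float:
    """Penalized log-likelihood maximized over all coefficients but beta_j."""
    fit = fit_firth(X, y, tau=tau, fixed={j: value}, beta0=beta0,
                    check_rank=False)
    return fit.loglik


def profile_ci_and_p(
    X: np.ndarray,
    y: np.ndarray,
    fit: FirthFit,
    j: int,
    level: float = 0.95,
    bound: float = 20.0,
) -> tuple[tuple[float, float], float, bool]:
    """Profile-penalized-likelihood CI and LRT p-value for coefficient j.

    Returns ``((lo, hi), p_value, open_interval)`` on the log-odds scale;
    a limit not bracketed within ``+/- bound`` is reported as +/- inf with
    ``open_interval=True``.
    """
    tau = fit.tau
    target = fit.loglik - 0.5 * chi2.ppf(level, df=1)
    bj = fit.beta[j]

    def deficit(b: float) -> float:
        return profile_loglik(X, y, j, b, tau=tau, beta0=fit.beta) - target

    def find_limit(direction: int) -> float:
        lo_b, f_lo = bj, fit.loglik - target  # > 0 at the optimum
        step = 0.25
        while True:
            hi_b = lo_b + direction * step
            if abs(hi_b - bj) > bound:
                return direction * np.inf
            f_hi = deficit(hi_b)
            if f_hi < 0.0:
                a, b = sorted((lo_b, hi_b))
                return brentq(deficit, a, b, xtol=1e-6)
            lo_b, f_lo = hi_b, f_hi
            step *= 2.0

    lo = find_limit(-1)
    hi = find_limit(+1)
    ll0 = profile_loglik(X, y, j, 0.0, tau=tau, beta0=fit.beta)
    lr = max(0.0, 2.0 * (fit.loglik - ll0))
    p = float(chi2.sf(lr, df=1))
    return (float(lo), float(hi)), max(p, np.finfo(float).tiny), bool(
        np.isinf(lo) or np.isinf(hi)
    )


def wald_ci_and_p(fit: FirthFit, j: int, level: float = 0.95):
    """Wald interval and p from the penalized-likelihood Fisher information."""
    from scipy.stats import norm

    se = fit.wald_se()[j]
    z = norm.ppf(0.5 + level / 2.0)
    b = fit.beta[j]
    p = float(2.0 * norm.sf(abs(b) / se)) if se > 0 else 1.0
    return (b - z * se, b + z * se), max(p, np.finfo(float).tiny)
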