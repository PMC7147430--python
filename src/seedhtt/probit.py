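"""Maximum-likelihood binomial probit regression.

Both threshold models reduce, for a fixed value of their profiled constant,
to a two-parameter probit regression of cumulative germinated counts on a
scalar predictor: the probability that a seed has germinated by scoring time
t is Phi(intercept + slope * x), with x built from water potential, time and
(for the pooled model) temperature.  This module owns that regression: a
Fisher-scoring Newton iteration on the exact binomial log-likelihood, with a
derivative-free fallback, plus the probit-scale R^2 used as a fit diagnostic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import gammaln, ndtr, ndtri

__all__ = ["ProbitFit", "probit", "inverse_probit", "fit_probit", "binomial_loglik"]

_P_CLIP = 1e-12
_SLOPE_SEPARATION = 1e3  # |slope| beyond this flags quasi-complete separation


def probit(p):
    """Standard normal quantile Phi^{-1}(p) for p in (0, 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any((arr <= 0) | (arr >= 1)):
        raise ValueError("probit requires 0 < p < 1")
    out = ndtri(arr)
    return float(out) if out.ndim == 0 else out


def inverse_probit(z):
    """Standard normal CDF Phi(z); inverse of :func:`probit`."""
    out = ndtr(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


@dataclass
class ProbitFit:
    """Result of a binomial probit regression.

    ``r_squared`` is the squared Pearson correlation between observed and
    fitted probit-transformed fractions over cells with fraction strictly
    inside (0, 1); it is NaN when fewer than two such cells exist.  This is a
    reporting convention, not part of the likelihood.
    """

    intercept: float
    slope: float
    log_likelihood: float
    r_squared: float
    n_cells: int
    converged: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "log_likelihood": self.log_likelihood,
            "r_squared": None if math.isnan(self.r_squared) else self.r_squared,
            "n_cells": self.n_cells,
            "converged": self.converged,
            "message": self.message,
        }


def binomial_loglik(x, successes, trials, intercept, slope) -> float:
    """Exact binomial log-likelihood of success probability Phi(a + b x)."""
    x = np.asarray(x, float)
    s = np.asarray(successes, float)
    n = np.asarray(trials, float)
    p = np.clip(ndtr(intercept + slope * x), _P_CLIP, 1 - _P_CLIP)
    const = np.sum(gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1))
    return float(const + np.sum(s * np.log(p) + (n - s) * np.log1p(-p)))


def _kernel(eta, s, n):
    p = np.clip(ndtr(eta), _P_CLIP, 1 - _P_CLIP)
    return p, float(np.sum(s * np.log(p) + (n - s) * np.log1p(-p)))


def fit_probit(x, successes, trials, start=None, tol=1e-8, max_iter=200) -> ProbitFit:
    """Fit Phi(intercept + slope * x) to binomial counts by maximum likelihood.

    Parameters
    ----------
    x : array-like
        Predictor per cell; at least two distinct values required.
    successes, trials : array-like
        Binomial counts per cell, 0 <= successes <= trials.
    start : (intercept, slope), optional
        Warm start for the Newton iteration.

    Notes
    -----
    Fisher scoring on the exact log-likelihood with step halving; convergence
    at 1e-8 on the log-likelihood.  If the iteration fails (singular
    information, separation-driven divergence) a Nelder-Mead fallback runs and
    the fit is flagged ``converged=False`` when the slope diverges, rather
    than raising: completely separated data have no finite ML optimum.
    """
    x = np.asarray(x, dtype=float).ravel()
    s = np.asarray(successes, dtype=float).ravel()
    n = np.asarray(trials, dtype=float).ravel()
    if not (x.shape == s.shape == n.shape):
        raise ValueError("x, successes, trials must have equal length")
    if x.size == 0:
        raise ValueError("empty data")
    if np.any(s < 0) or np.any(s > n):
        raise ValueError("need 0 <= successes <= trials")
    if np.unique(x).size < 2:
        raise ValueError("slope is unidentifiable: need at least two distinct x")

    X = np.column_stack([np.ones_like(x), x])
    const = float(np.sum(gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)))

    if start is None:
        overall = np.clip(s.sum() / n.sum(), 1e-6, 1 - 1e-6)
        beta = np.array([ndtri(overall), 0.0])
    else:
        beta = np.array(start, dtype=float)

    _, ll = _kernel(X @ beta, s, n)
    converged = False
    message = ""
    for _ in range(max_iter):
        eta = X @ beta
        p = np.clip(ndtr(eta), _P_CLIP, 1 - _P_CLIP)
        phi = np.exp(-0.5 * eta**2) / math.sqrt(2 * math.pi)
        v = p * (1 - p)
        score = X.T @ ((s - n * p) * phi / v)
        w = n * phi**2 / v
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step halving to guarantee likelihood ascent
        new_ll = -np.inf
        for _half in range(40):
            cand = beta + step
            _, new_ll = _kernel(X @ cand, s, n)
            if new_ll >= ll - 1e-13:
                break
            step *= 0.5
        if new_ll < ll - 1e-13:
            break
        beta_new, delta = cand, new_ll - ll
        beta, ll = beta_new, new_ll
        if abs(delta) < tol:
            converged = True
            break

    if not converged or not np.all(np.isfinite(beta)):
        # derivative-free fallback on the same objective
        res = optimize.minimize(
            lambda b: -_kernel(X @ b, s, n)[1],
            beta if np.all(np.isfinite(beta)) else np.array([0.0, 0.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        if -res.fun >= ll:
            beta, ll = res.x, -res.fun
        converged = bool(res.success) or converged

    if _is_separated(x, s, n) or abs(beta[1]) > _SLOPE_SEPARATION \
            or not np.all(np.isfinite(beta)):
        converged = False
        message = "possible complete separation: no finite ML optimum"
    elif not converged:
        message = "did not reach the convergence tolerance"

    r2 = _probit_r_squared(x, s, n, beta)
    return ProbitFit(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        log_likelihood=ll + const,
        r_squared=r2,
        n_cells=int(x.size),
        converged=converged,
        message=message,
    )


def _is_separated(x, s, n) -> bool:
    # all-0 fractions below some x and all-1 fractions above (either
    # direction): the likelihood has no finite maximum
    frac = s / n
    if np.any((frac > 0) & (frac < 1)):
        return False
    f_sorted = frac[np.argsort(x, kind="stable")]
    d = np.diff(f_sorted)
    return bool(np.all(d >= 0) or np.all(d <= 0)) and f_sorted[0] != f_sorted[-1]


def _probit_r_squared(x, s, n, beta) -> float:
    frac = s / n
    mask = (frac > 0) & (frac < 1)
    if mask.sum() < 2:
        return float("nan")
    obs = ndtri(frac[mask])
    fit = beta[0] + beta[1] * x[mask]
    if np.std(obs) == 0 or np.std(fit) == 0:
        return float("nan")
    r = np.corrcoef(obs, fit)[0, 1]
    return float(r**2)
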