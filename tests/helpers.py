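"""Independent oracles used by the tests.

These deliberately avoid the package's own Newton/golden-section machinery:
the grid searches enumerate the likelihood directly, and the GLM cross-check
goes through statsmodels.
"""

import numpy as np

from seedhtt.probit import binomial_loglik


def grid_probit(x, s, n, b0_range=(-6.0, 6.0), b1_range=(-6.0, 6.0),
                coarse=0.05, fine=1e-3):
    """Brute-force 2-D grid search of the binomial probit likelihood.

    Coarse pass over the full ranges, then a full fine-resolution pass in a
    +-2*coarse window around the coarse optimum.  The probit likelihood is
    concave in (intercept, slope), so the two-stage enumeration finds the
    global grid optimum at ``fine`` resolution.
    """
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    n = np.asarray(n, float)

    def best_on(b0s, b1s):
        from scipy.special import ndtr

        B0, B1 = np.meshgrid(b0s, b1s, indexing="ij")
        eta = B0[..., None] + B1[..., None] * x  # (n0, n1, cells)
        p = np.clip(ndtr(eta), 1e-12, 1 - 1e-12)
        ll = (s * np.log(p) + (n - s) * np.log1p(-p)).sum(axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        return float(B0[i, j]), float(B1[i, j]), float(ll[i, j])

    b0, b1, _ = best_on(np.arange(*b0_range, coarse), np.arange(*b1_range, coarse))
    win = 2 * coarse
    b0, b1, ll = best_on(np.arange(b0 - win, b0 + win, fine),
                         np.arange(b1 - win, b1 + win, fine))
    return b0, b1, ll + _binom_const(s, n)


def _binom_const(s, n):
    from scipy.special import gammaln

    return float(np.sum(gammaln(n + 1) - gammaln(s + 1) - gammaln(n - s + 1)))


def statsmodels_probit(x, s, n):
    """Binomial probit GLM via statsmodels: (intercept, slope, loglik)."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, float))
    endog = np.column_stack([s, np.asarray(n) - np.asarray(s)])
    res = sm.GLM(endog, X, family=sm.families.Binomial(sm.families.links.Probit())).fit()
    return float(res.params[0]), float(res.params[1]), float(res.llf)


def profiled_ht_grid(psi, t, s, n, theta_grid):
    """Exhaustive profiled search for the hydrotime constant.

    Inner probit solved with statsmodels (independent of the package's
    Newton); returns (theta, intercept, slope, loglik) at the grid optimum.
    """
    best = None
    for theta in theta_grid:
        b0, b1, ll = statsmodels_probit(psi - theta / t, s, n)
        if best is None or ll > best[3]:
            best = (float(theta), b0, b1, ll)
    return best


def profiled_htt_grid(T, psi, t, s, n, tb_grid, theta_grid):
    """Exhaustive (T_b, theta_HT) grid for the pooled sub-optimal model."""
    best = None
    for tb in tb_grid:
        denom = (T - tb) * t
        for theta in theta_grid:
            b0, b1, ll = statsmodels_probit(psi - theta / denom, s, n)
            if best is None or ll > best[4]:
                best = (float(tb), float(theta), b0, b1, ll)
    return best
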