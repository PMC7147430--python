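"""Shared fixtures: generating truths and noiseless model datasets."""

import numpy as np
import pytest

from seedhtt import HTParams, HTTParams
from seedhtt.probit import inverse_probit


@pytest.fixture(scope="session")
def ht20() -> HTParams:
    """Hydrotime parameters typical of this seed lot at 20 C."""
    return HTParams(temperature=20.0, theta_H=4.2, psi_b50=-0.49, sigma_psib=0.27)


@pytest.fixture(scope="session")
def ht24() -> HTParams:
    return HTParams(temperature=24.0, theta_H=3.0, psi_b50=-0.40, sigma_psib=0.28)


@pytest.fixture(scope="session")
def htt_truth() -> HTTParams:
    """Full hydrothermal truth with both branches."""
    return HTTParams(theta_HT=43.9, t_b=7.0, psi_b50=-0.67, sigma_psib_sub=0.28,
                     t_o=20.5, k_T=0.1)


PSI_LEVELS = (0.0, -0.2, -0.4, -0.6)
SUB_TEMPS = (11.0, 15.0, 20.0)
SUPRA_TEMPS = (24.0, 28.0)


def noiseless_ht_cells(params: HTParams, psis=PSI_LEVELS, days=None, trials=10**6):
    """Exact model fractions rounded onto huge binomial trials.

    The ML optimum of these cells is the generating parameter triple up to
    rounding, so fits on them check the optimizer, not sampling noise.
    """
    if days is None:
        days = np.arange(1.0, 21.0)
    psi_c, t_c, s_c, n_c = [], [], [], []
    for psi in psis:
        for t in days:
            z = (psi - params.theta_H / t - params.psi_b50) / params.sigma_psib
            p = inverse_probit(z)
            psi_c.append(psi)
            t_c.append(t)
            s_c.append(round(trials * p))
            n_c.append(trials)
    return (np.array(psi_c), np.array(t_c), np.array(s_c, float), np.array(n_c, float))


def noiseless_htt_cells(params: HTTParams, temps=SUB_TEMPS, psis=PSI_LEVELS,
                        days=None, trials=10**6):
    """Sub-optimal-branch analogue of :func:`noiseless_ht_cells`."""
    if days is None:
        days = np.arange(1.0, 26.0)
    T_c, psi_c, t_c, s_c, n_c = [], [], [], [], []
    for T in temps:
        for psi in psis:
            for t in days:
                x = psi - params.theta_HT / ((T - params.t_b) * t)
                p = inverse_probit((x - params.psi_b50) / params.sigma_psib_sub)
                T_c.append(T)
                psi_c.append(psi)
                t_c.append(t)
                s_c.append(round(trials * p))
                n_c.append(trials)
    return (np.array(T_c), np.array(psi_c), np.array(t_c),
            np.array(s_c, float), np.array(n_c, float))


def cells_to_timecourses(T, psi, t, s, n):
    """Pack per-cell arrays into GerminationTimeCourse objects (one dish per
    (T, psi), days ordered)."""
    from seedhtt import GerminationTimeCourse

    courses = []
    for Tv in np.unique(T):
        for pv in np.unique(psi[T == Tv]):
            m = (T == Tv) & (psi == pv)
            order = np.argsort(t[m])
            # noiseless fractions are monotone in t, so cumulative holds
            courses.append(GerminationTimeCourse(
                temperature=float(Tv), water_potential=float(pv), replicate="r1",
                n_seeds=int(n[m][0]), days=t[m][order],
                cumulative=s[m][order].astype(int)))
    return courses
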