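"""Per-temperature hydrotime model of seed germination.

The hydrotime model postulates that at a fixed temperature the g-th
percentile of a seed population germinates when the accumulated hydrotime

    theta_H = [psi - psi_b(g)] * t_g

reaches a population constant theta_H (MPa d), where the base water
potential psi_b(g) is normally distributed over seeds with median
psi_b(50) and standard deviation sigma_psib.  Equivalently, the cumulative
germinated fraction at time t under water potential psi satisfies

    probit(g) = [(psi - theta_H / t) - psi_b(50)] / sigma_psib,

so for a fixed theta_H the model is a binomial probit regression on the
predictor x = psi - theta_H / t.  theta_H is profiled: a golden-section
search over theta_H maximises the profiled binomial log-likelihood, and the
best probit fit yields psi_b(50) = -intercept/slope and
sigma_psib = 1/slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._optimize import golden_section_min
from .exceptions import ModelMisfitError, NonIdentifiableError
from .probit import ProbitFit, fit_probit, inverse_probit, probit

__all__ = [
    "HTParams",
    "cells_from_timecourses",
    "fit_ht",
    "predict_time_to_g",
    "predict_fraction_at_time",
    "normalize_time",
    "thermal_time_scale",
    "psi_b_quantile",
]

NEVER = math.inf
"""Marker returned by time predictions when the fraction never germinates."""


@dataclass
class HTParams:
    """Fitted (or generating) hydrotime parameters at one temperature.

    theta_H in MPa d, psi_b50 in MPa, sigma_psib in MPa; ``fit`` holds the
    underlying probit regression when the parameters come from data.
    """

    temperature: float
    theta_H: float
    psi_b50: float
    sigma_psib: float
    fit: ProbitFit | None = None

    def __post_init__(self) -> None:
        if self.theta_H <= 0:
            raise ValueError(f"theta_H must be > 0, got {self.theta_H}")
        if self.sigma_psib <= 0:
            raise ValueError(f"sigma_psib must be > 0, got {self.sigma_psib}")

    def to_dict(self) -> dict:
        return {
            "temperature_C": self.temperature,
            "theta_H": self.theta_H,
            "psi_b50": self.psi_b50,
            "sigma_psib": self.sigma_psib,
            "fit": self.fit.to_dict() if self.fit else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HTParams":
        return cls(
            temperature=d["temperature_C"],
            theta_H=d["theta_H"],
            psi_b50=d["psi_b50"],
            sigma_psib=d["sigma_psib"],
        )


def cells_from_timecourses(timecourses):
    """Flatten time courses into per-(dish, scoring day) binomial cells.

    Every scoring-day x dish cell enters the likelihood as an independent
    binomial observation (the repeated-probit layout standard for
    population-based threshold models); replicates are pooled, not averaged,
    and all-zero early cells are retained — they carry threshold information.

    Returns (temperature, psi, t, successes, trials) arrays, one entry per cell.
    """
    temps, psis, ts, ss, ns = [], [], [], [], []
    for tc in timecourses:
        for d, c in zip(tc.days, tc.cumulative):
            temps.append(tc.temperature)
            psis.append(tc.water_potential)
            ts.append(d)
            ss.append(c)
            ns.append(tc.n_seeds)
    return (
        np.asarray(temps, float),
        np.asarray(psis, float),
        np.asarray(ts, float),
        np.asarray(ss, float),
        np.asarray(ns, float),
    )


def fit_ht(
    timecourses,
    theta_bounds: tuple[float, float] = (0.05, 50.0),
    theta_tol: float = 1e-3,
) -> HTParams:
    """Fit the hydrotime model to all water-potential levels at one temperature.

    theta_H is profiled by golden-section search on ``theta_bounds`` (MPa d,
    refined to ``theta_tol``); for each candidate every cell contributes a
    binomial probit observation with predictor x = psi - theta_H / t.

    Raises
    ------
    ValueError
        Fewer than two distinct water potentials, or mixed temperatures.
    ModelMisfitError
        No germination anywhere, or non-positive slope at the optimum
        (germination decreasing in psi - theta_H/t contradicts the model).
    NonIdentifiableError
        Degenerate profile: the probit slope vanishes, so the threshold
        distribution is unconstrained (e.g. all levels germinate identically).
    """
    tcs = list(timecourses)
    temps = {tc.temperature for tc in tcs}
    if len(temps) != 1:
        raise ValueError(f"fit_ht expects a single temperature, got {sorted(temps)}")
    if len({tc.water_potential for tc in tcs}) < 2:
        raise ValueError("need at least two distinct water-potential levels")
    _, psi, t, s, n = cells_from_timecourses(tcs)
    if s.sum() == 0:
        raise ModelMisfitError("no germination observed at any water potential")

    def nll(theta: float) -> float:
        return -fit_probit(psi - theta / t, s, n).log_likelihood

    theta, _ = golden_section_min(nll, *theta_bounds, tol=theta_tol)
    best = fit_probit(psi - theta / t, s, n)
    if abs(best.slope) < 1e-6:
        raise NonIdentifiableError(
            "degenerate profile: probit slope ~ 0, threshold spread unidentifiable"
        )
    if best.slope < 0:
        raise ModelMisfitError(
            "fitted germination decreases in psi - theta_H/t; hydrotime model misfit"
        )
    return HTParams(
        temperature=temps.pop(),
        theta_H=float(theta),
        psi_b50=-best.intercept / best.slope,
        sigma_psib=1.0 / best.slope,
        fit=best,
    )


def psi_b_quantile(params: HTParams, g: float) -> float:
    """Base water potential of the g-th percentile: psi_b50 + sigma * probit(g)."""
    return params.psi_b50 + params.sigma_psib * probit(g)


def predict_time_to_g(params: HTParams, psi: float, g: float) -> float:
    """Time (days) for fraction g to germinate at water potential psi.

    Returns ``NEVER`` (inf) when psi does not exceed the percentile's base
    water potential, i.e. no hydrotime accumulates.
    """
    psi_bg = psi_b_quantile(params, g)
    if psi <= psi_bg:
        return NEVER
    return params.theta_H / (psi - psi_bg)


def predict_fraction_at_time(params: HTParams, psi: float, t) -> float | np.ndarray:
    """Cumulative germinated fraction at time t (days) under water potential psi.

    Phi((psi - theta_H/t - psi_b50) / sigma_psib); non-decreasing in t with
    limit Phi((psi - psi_b50)/sigma_psib) as t -> inf.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    z = (psi - params.theta_H / t - params.psi_b50) / params.sigma_psib
    return inverse_probit(z)


def normalize_time(t_g: float, psi: float, g: float, params: HTParams) -> float:
    """Map a germination time at reduced psi onto the pure-water time axis.

    The factor [1 - psi/psi_b(g)] rescales t_g so that, under the model, the
    same fraction g germinates at the normalized time in distilled water
    (psi = 0).  Undefined when psi_b(g) = 0 (threshold at pure water).
    """
    psi_bg = psi_b_quantile(params, g)
    if abs(psi_bg) < 1e-12:
        raise ZeroDivisionError(
            "psi_b(g) = 0: normalization factor degenerate at this percentile"
        )
    return (1.0 - psi / psi_bg) * t_g


def thermal_time_scale(t: float, temperature: float, t_b: float) -> float:
    """Thermal time (degree-days) accumulated in t days at a given temperature."""
    if temperature <= t_b:
        raise ValueError(
            f"temperature {temperature} must exceed the base temperature {t_b}"
        )
    return (temperature - t_b) * t
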