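"""Pooled hydrothermal-time model across temperature and water potential.

Below the optimum temperature T_o, germination of the g-th percentile
requires a fixed hydrothermal time

    theta_HT = (T - T_b) [psi - psi_b(g)] t_g        (sub-optimal branch)

with a single base temperature T_b and a normal psi_b(g) distribution shared
across temperatures.  Above T_o the base water potential of every percentile
rises linearly with temperature at rate K_T (MPa / degree C), producing a
ceiling temperature T_c(g) at which germination ceases:

    theta_HT = {psi - psi_b(g) - K_T (T - T_o)} (T_o - T_b) t_g   (supra branch)

where, following the convention that the threshold distribution and the
thermal-time factor are frozen at T_o, the thermal factor uses (T_o - T_b)
while the K_T shift uses the actual temperature.  The alternative reading
with an actual (T - T_b) factor is available via ``supra_thermal="actual"``.

Fitting is fully profiled probit regression: the sub-optimal branch grid-
searches T_b (0.1 degree resolution) with an inner golden-section search on
theta_HT; the supra-optimal branch fixes theta_HT/T_b from the sub fit and
grid-searches (T_o, K_T), accepting the likelihood-best pair whose implied
psi_b(50) and sigma match the sub-optimal estimates within declared
tolerances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from ._optimize import golden_section_min
from .data import fgp_table
from .exceptions import ModelMisfitError
from .hydrotime import NEVER, cells_from_timecourses
from .probit import ProbitFit, fit_probit, probit

__all__ = [
    "HTTParams",
    "fit_htt_suboptimal",
    "fit_htt_supraoptimal",
    "fit_htt",
    "ceiling_temperature",
    "predict_htt_time_to_g",
    "predict_htt_fraction_at_time",
    "classify_branch",
]

_SUPRA_CONVENTIONS = ("capped", "actual")


@dataclass
class HTTParams:
    """Hydrothermal-time parameters; supra-optimal fields are None until the
    supra-optimal branch has been fitted.

    theta_HT in MPa degC d; t_b, t_o, t_c50 in degC; psi_b50, sigma in MPa;
    k_T in MPa per degC.  ``supra_thermal`` records which thermal-factor
    convention the supra branch uses ("capped": T_o - T_b; "actual": T - T_b).
    """

    theta_HT: float
    t_b: float
    psi_b50: float
    sigma_psib_sub: float
    fit_sub: ProbitFit | None = None
    t_o: float | None = None
    k_T: float | None = None
    t_c50: float | None = None
    sigma_psib_supra: float | None = None
    fit_supra: ProbitFit | None = None
    supra_match_ok: bool | None = None
    t_b_on_boundary: bool = False
    supra_thermal: str = "capped"

    def __post_init__(self) -> None:
        if self.theta_HT <= 0:
            raise ValueError(f"theta_HT must be > 0, got {self.theta_HT}")
        if self.sigma_psib_sub <= 0:
            raise ValueError(f"sigma_psib_sub must be > 0, got {self.sigma_psib_sub}")
        if self.supra_thermal not in _SUPRA_CONVENTIONS:
            raise ValueError(f"supra_thermal must be one of {_SUPRA_CONVENTIONS}")
        if self.t_o is not None:
            if self.k_T is None or self.k_T <= 0:
                raise ValueError("supra-optimal branch requires k_T > 0")
            if not self.t_b < self.t_o:
                raise ValueError(f"need t_b < t_o, got {self.t_b} >= {self.t_o}")
            ident = self.t_o + (0.0 - self.psi_b50) / self.k_T
            if self.t_c50 is None:
                self.t_c50 = ident
            elif not math.isclose(self.t_c50, ident, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"t_c50={self.t_c50} violates the water ceiling identity "
                    f"t_o - psi_b50/k_T = {ident}"
                )
            if not self.t_o < self.t_c50:
                raise ValueError("need t_o < t_c50 (requires psi_b50 < 0)")

    def to_dict(self) -> dict:
        return {
            "theta_HT": self.theta_HT,
            "t_b": self.t_b,
            "psi_b50": self.psi_b50,
            "sigma_psib_sub": self.sigma_psib_sub,
            "t_o": self.t_o,
            "k_T": self.k_T,
            "t_c50": self.t_c50,
            "sigma_psib_supra": self.sigma_psib_supra,
            "supra_match_ok": self.supra_match_ok,
            "t_b_on_boundary": self.t_b_on_boundary,
            "supra_thermal": self.supra_thermal,
            "fit_sub": self.fit_sub.to_dict() if self.fit_sub else None,
            "fit_supra": self.fit_supra.to_dict() if self.fit_supra else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HTTParams":
        return cls(
            theta_HT=d["theta_HT"],
            t_b=d["t_b"],
            psi_b50=d["psi_b50"],
            sigma_psib_sub=d["sigma_psib_sub"],
            t_o=d.get("t_o"),
            k_T=d.get("k_T"),
            t_c50=d.get("t_c50"),
            sigma_psib_supra=d.get("sigma_psib_supra"),
            supra_match_ok=d.get("supra_match_ok"),
            supra_thermal=d.get("supra_thermal", "capped"),
        )


def classify_branch(temperature: float, t_o: float) -> str:
    """Assign a temperature to the "sub" (T <= T_o) or "supra" (T > T_o) branch."""
    return "sub" if temperature <= t_o else "supra"


def fit_htt_suboptimal(
    timecourses,
    t_b_min: float = 0.0,
    t_b_max: float | None = None,
    t_b_step: float = 0.1,
    theta_bounds: tuple[float, float] = (0.5, 500.0),
    theta_tol: float = 1e-3,
    t_b_search: str = "refine",
) -> HTTParams:
    """Fit the sub-optimal hydrothermal-time branch by nested profiling.

    Outer grid on T_b (``t_b_step`` resolution on [t_b_min, t_b_max], default
    upper bound min(T) - 0.5), inner golden-section on theta_HT; for each
    (T_b, theta_HT) every cell yields predictor
    x = psi - theta_HT / ((T - T_b) t) for a binomial probit regression.

    ``t_b_search="refine"`` (default) runs a coarse 1-degree pass then the
    full ``t_b_step`` resolution within +-1.5 degrees of the coarse optimum
    (the profiled likelihood in T_b is smooth and unimodal here);
    ``"exhaustive"`` evaluates the entire fine grid.

    A maximum on the grid boundary raises a warning and sets
    ``t_b_on_boundary``; a non-positive slope raises :class:`ModelMisfitError`.
    """
    tcs = list(timecourses)
    temps = sorted({tc.temperature for tc in tcs})
    if len(temps) < 2:
        raise ValueError(
            "single temperature: T_b and theta_HT are confounded — use fit_ht"
        )
    if len({tc.water_potential for tc in tcs}) < 2:
        raise ValueError("need at least two distinct water-potential levels")
    if t_b_search not in ("refine", "exhaustive"):
        raise ValueError("t_b_search must be 'refine' or 'exhaustive'")
    if t_b_max is None:
        t_b_max = temps[0] - 0.5
    if t_b_max <= t_b_min:
        raise ValueError(f"empty T_b grid: [{t_b_min}, {t_b_max}]")
    T, psi, t, s, n = cells_from_timecourses(tcs)
    if s.sum() == 0:
        raise ModelMisfitError("no germination observed anywhere")

    def profile(tb: float) -> tuple[float, float]:
        """Profiled log-likelihood over theta_HT at fixed T_b."""
        denom = (T - tb) * t

        def nll(theta: float) -> float:
            return -fit_probit(psi - theta / denom, s, n).log_likelihood

        theta, fmin = golden_section_min(nll, *theta_bounds, tol=theta_tol)
        return theta, -fmin

    fine = np.round(np.arange(t_b_min, t_b_max + t_b_step / 2, t_b_step), 10)
    if t_b_search == "exhaustive":
        candidates = fine
    else:
        coarse = np.unique(np.append(np.arange(t_b_min, t_b_max, 1.0), t_b_max))
        prof_c = [profile(tb)[1] for tb in coarse]
        center = coarse[int(np.argmax(prof_c))]
        candidates = fine[np.abs(fine - center) <= 1.5 + 1e-9]

    best_tb, best_theta, best_ll = None, None, -np.inf
    for tb in candidates:
        theta, ll = profile(tb)
        if ll > best_ll:
            best_tb, best_theta, best_ll = float(tb), theta, ll

    on_boundary = math.isclose(best_tb, t_b_min) or math.isclose(best_tb, t_b_max)
    if on_boundary:
        warnings.warn(
            f"profiled T_b = {best_tb} lies on the search boundary "
            f"[{t_b_min}, {t_b_max}]; estimate may be unreliable",
            stacklevel=2,
        )
    fit = fit_probit(psi - best_theta / ((T - best_tb) * t), s, n)
    if fit.slope <= 0:
        raise ModelMisfitError("non-positive probit slope at the optimum")
    return HTTParams(
        theta_HT=float(best_theta),
        t_b=best_tb,
        psi_b50=-fit.intercept / fit.slope,
        sigma_psib_sub=1.0 / fit.slope,
        fit_sub=fit,
        t_b_on_boundary=on_boundary,
    )


def _supra_predictor(T, psi, t, theta_HT, t_b, t_o, k_T, convention):
    thermal = (t_o - t_b) if convention == "capped" else (T - t_b)
    return psi - theta_HT / (thermal * t) - k_T * (T - t_o)


def fit_htt_supraoptimal(
    timecourses,
    sub: HTTParams,
    t_o_bounds: tuple[float, float] | None = None,
    t_o_step: float = 0.1,
    k_t_max: float = 1.0,
    k_t_step: float = 0.01,
    match_tol_psi_b50: float = 0.02,
    match_tol_sigma: float = 0.05,
    supra_thermal: str = "capped",
) -> HTTParams:
    """Fit the supra-optimal branch: grid search on (T_o, K_T).

    theta_HT and T_b are fixed from the completed sub-optimal fit.  For each
    candidate pair every supra-optimal cell yields predictor
    x = psi - theta_HT/(thermal * t) - K_T (T - T_o) for a probit regression;
    among pairs whose implied psi_b(50) and sigma agree with the sub-optimal
    estimates within the match tolerances, the likelihood-best pair wins.  If
    no pair matches, the overall likelihood-best pair is returned with
    ``supra_match_ok=False``.

    ``t_o_bounds`` defaults to (min supra T - 4, min supra T); pass the
    largest sub-optimal tested temperature explicitly when known — T_o is
    only identified between tested temperatures.
    """
    tcs = list(timecourses)
    if not tcs:
        raise ValueError("no supra-optimal time courses supplied")
    if supra_thermal not in _SUPRA_CONVENTIONS:
        raise ValueError(f"supra_thermal must be one of {_SUPRA_CONVENTIONS}")
    T, psi, t, s, n = cells_from_timecourses(tcs)
    t_min_supra = float(T.min())
    if t_o_bounds is None:
        t_o_bounds = (t_min_supra - 4.0, t_min_supra)
    lo, hi = t_o_bounds
    if not sub.t_b < lo:
        raise ValueError(f"T_o search range must lie above t_b={sub.t_b}")
    t_o_grid = np.round(np.arange(lo, hi + t_o_step / 2, t_o_step), 10)
    k_t_grid = np.round(np.arange(k_t_step, k_t_max + k_t_step / 2, k_t_step), 10)

    best = None  # (ll, t_o, k_T, fit)
    best_matched = None
    warm = None
    for t_o in t_o_grid:
        for k_T in k_t_grid:
            x = _supra_predictor(T, psi, t, sub.theta_HT, sub.t_b, t_o, k_T, supra_thermal)
            fit = fit_probit(x, s, n, start=warm)
            warm = (fit.intercept, fit.slope) if fit.converged else None
            if fit.slope <= 0:
                continue
            ll = fit.log_likelihood
            cand = (ll, float(t_o), float(k_T), fit)
            if best is None or ll > best[0]:
                best = cand
            psi_b50_s = -fit.intercept / fit.slope
            sigma_s = 1.0 / fit.slope
            if (
                abs(psi_b50_s - sub.psi_b50) <= match_tol_psi_b50
                and abs(sigma_s - sub.sigma_psib_sub) <= match_tol_sigma
            ):
                if best_matched is None or ll > best_matched[0]:
                    best_matched = cand
    if best is None:
        raise ModelMisfitError("no (T_o, K_T) pair produced a positive-slope fit")
    matched = best_matched is not None
    ll, t_o, k_T, fit = best_matched if matched else best
    return replace(
        sub,
        t_o=t_o,
        k_T=k_T,
        t_c50=None,  # recomputed from the ceiling identity in __post_init__
        sigma_psib_supra=1.0 / fit.slope,
        fit_supra=fit,
        supra_match_ok=matched,
        supra_thermal=supra_thermal,
    )


def fit_htt(timecourses, provisional_t_o: float | None = None, **kwargs) -> HTTParams:
    """Fit both branches on a factorial dataset.

    The data are partitioned at a provisional optimum temperature — by
    default the tested temperature with the highest mean final germination
    percentage; the final T_o comes from the supra-optimal grid search on
    (largest sub-optimal T, smallest supra-optimal T).  Keyword arguments are
    routed to the branch fitters by prefix (``sub__``/``supra__``).
    """
    tcs = list(timecourses)
    if provisional_t_o is None:
        fgp = fgp_table(tcs)
        mean_by_t = fgp.groupby("temperature_C")["mean_fgp"].mean()
        provisional_t_o = float(mean_by_t.idxmax())
    branches = {tc: classify_branch(tc.temperature, provisional_t_o) for tc in tcs}
    sub_tcs = [tc for tc in tcs if branches[tc] == "sub"]
    supra_tcs = [tc for tc in tcs if branches[tc] == "supra"]
    sub_kwargs = {k[5:]: v for k, v in kwargs.items() if k.startswith("sub__")}
    supra_kwargs = {k[7:]: v for k, v in kwargs.items() if k.startswith("supra__")}
    sub = fit_htt_suboptimal(sub_tcs, **sub_kwargs)
    if not supra_tcs:
        return sub
    t_max_sub = max(tc.temperature for tc in sub_tcs)
    t_min_supra = min(tc.temperature for tc in supra_tcs)
    supra_kwargs.setdefault("t_o_bounds", (t_max_sub, t_min_supra))
    return fit_htt_supraoptimal(supra_tcs, sub, **supra_kwargs)


def _psi_b_quantile_sub(params: HTTParams, g: float) -> float:
    # the supra branch freezes the threshold distribution at T_o, so the
    # sub-optimal sigma parameterises psi_b(g) everywhere
    return params.psi_b50 + params.sigma_psib_sub * probit(g)


def ceiling_temperature(params: HTTParams, psi: float = 0.0, g: float = 0.5) -> float:
    """Ceiling temperature T_c(g): where the K_T-shifted threshold reaches psi.

    Solves psi - psi_b(g) - K_T (T - T_o) = 0, i.e.
    T_c(g) = T_o + (psi - psi_b(g)) / K_T.  Monotone decreasing in g.
    """
    if params.t_o is None:
        raise ValueError("supra-optimal branch not fitted: no T_o/K_T available")
    if psi > 0:
        raise ValueError("psi must be <= 0 MPa")
    psi_bg = _psi_b_quantile_sub(params, g)
    if psi < psi_bg:
        raise ValueError(
            f"psi={psi} below psi_b(g)={psi_bg:.4f}: fraction {g} cannot "
            "germinate at any temperature (no supra-optimal window)"
        )
    return params.t_o + (psi - psi_bg) / params.k_T


def predict_htt_time_to_g(
    params: HTTParams, temperature: float, psi: float, g: float
) -> float:
    """Days for fraction g to germinate at (temperature, psi); inf if never.

    Sub-optimal branch (T <= T_o): t = theta_HT / ((T - T_b)(psi - psi_b(g))).
    Supra-optimal branch: the threshold shifts to psi_b(g) + K_T (T - T_o) and
    the thermal factor follows the fitted convention.  Returns ``NEVER`` when
    T <= T_b, T at/above the percentile's ceiling, or psi at/below the
    (shifted) threshold.
    """
    if not 0 < g < 1:
        raise ValueError("g must be in (0, 1)")
    if temperature <= params.t_b:
        return NEVER
    psi_bg = _psi_b_quantile_sub(params, g)
    if params.t_o is None or temperature <= params.t_o:
        if psi <= psi_bg:
            return NEVER
        return params.theta_HT / ((temperature - params.t_b) * (psi - psi_bg))
    threshold = psi_bg + params.k_T * (temperature - params.t_o)
    # tolerance soaks up float residue at the exact ceiling temperature
    if psi - threshold <= 1e-12:
        return NEVER  # includes temperature >= T_c(g)
    thermal = (
        params.t_o - params.t_b
        if params.supra_thermal == "capped"
        else temperature - params.t_b
    )
    return params.theta_HT / (thermal * (psi - threshold))


def predict_htt_fraction_at_time(
    params: HTTParams, temperature: float, psi: float, t
) -> float | np.ndarray:
    """Cumulative germinated fraction at time t under the fitted HTT model."""
    from .probit import inverse_probit

    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    if temperature <= params.t_b:
        return np.zeros_like(t) if t.ndim else 0.0
    if params.t_o is None or temperature <= params.t_o:
        x = psi - params.theta_HT / ((temperature - params.t_b) * t)
    else:
        x = _supra_predictor(
            temperature, psi, t, params.theta_HT, params.t_b,
            params.t_o, params.k_T, params.supra_thermal,
        )
    sigma = params.sigma_psib_sub
    return inverse_probit((x - params.psi_b50) / sigma)
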