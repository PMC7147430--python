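"""Forward simulation of interval-censored germination experiments.

Each seed draws its base water potential psi_b from Normal(psi_b50,
sigma_psib).  Given the dish's (temperature, water potential) condition the
threshold model then fixes the seed's germination time exactly — there is no
extra timing noise, so the generator is the precise forward model of the
fitted likelihood and parameter-recovery tests are clean.  Observation is
interval-censored at the scoring grid (a seed germinating in (d-1, d] is
scored on day d) and truncated by the bench protocol: scoring stops after a
run of consecutive zero-germination days (once germination has begun) or at
``max_days``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import GerminationTimeCourse
from .hydrotime import HTParams
from .hydrothermal import HTTParams

__all__ = [
    "DEFAULT_DESIGN",
    "SimulationConfig",
    "sample_base_potentials",
    "latent_times",
    "simulate_dish",
    "simulate_experiment",
]

DEFAULT_TEMPERATURES = (11.0, 15.0, 20.0, 24.0, 28.0)
DEFAULT_WATER_POTENTIALS = (0.0, -0.2, -0.4, -0.6)
DEFAULT_DESIGN = tuple(
    (T, psi) for T in DEFAULT_TEMPERATURES for psi in DEFAULT_WATER_POTENTIALS
)
"""The study factorial: 5 temperatures x 4 water potentials."""


@dataclass
class SimulationConfig:
    """Generating truth plus experimental design for a simulated assay.

    Defaults mirror the emulated protocol: 4 replicate dishes of 100 seeds
    per condition, daily scoring, termination after 3 consecutive days with
    no new germination, and a 60-day cap.  ``termination_consecutive_zero_days
    = None`` disables the termination rule; ``max_days = inf`` disables the
    cap (useful for studying the uncensored model).
    """

    truth: HTParams | HTTParams
    design: tuple = DEFAULT_DESIGN
    replicates: int = 4
    n_seeds: int = 100
    scoring_interval: float = 1.0
    termination_consecutive_zero_days: int | None = 3
    max_days: float = 60.0
    rng_seed: int = 0
    align_final_day: bool = False

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError(f"n_seeds must be >= 1, got {self.n_seeds}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.scoring_interval <= 0:
            raise ValueError("scoring_interval must be positive")
        if self.max_days < self.scoring_interval:
            raise ValueError("max_days must be at least one scoring interval")

    def manifest(self) -> dict:
        from . import __version__

        return {
            "package": "seedhtt",
            "version": __version__,
            "model": "HT" if isinstance(self.truth, HTParams) else "HTT",
            "truth": self.truth.to_dict(),
            "design": [list(c) for c in self.design],
            "replicates": self.replicates,
            "n_seeds": self.n_seeds,
            "scoring_interval": self.scoring_interval,
            "termination_consecutive_zero_days": self.termination_consecutive_zero_days,
            "max_days": self.max_days,
            "rng_seed": self.rng_seed,
            "align_final_day": self.align_final_day,
        }


def sample_base_potentials(truth, n_seeds: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-seed base water potentials psi_b ~ Normal(psi_b50, sigma_psib)."""
    sigma = truth.sigma_psib if isinstance(truth, HTParams) else truth.sigma_psib_sub
    return rng.normal(truth.psi_b50, sigma, size=n_seeds)


def latent_times(truth, temperature: float, psi: float, psi_b: np.ndarray) -> np.ndarray:
    """Exact germination times implied by the threshold model; inf = never.

    HT truth: t = theta_H / (psi - psi_b).  HTT truth: below T_o,
    t = theta_HT / ((T - T_b)(psi - psi_b)); above T_o the threshold shifts by
    K_T (T - T_o) and the thermal factor follows ``truth.supra_thermal``.
    """
    psi_b = np.asarray(psi_b, dtype=float)
    out = np.full(psi_b.shape, math.inf)
    if isinstance(truth, HTParams):
        margin = psi - psi_b
        ok = margin > 0
        out[ok] = truth.theta_H / margin[ok]
        return out
    if temperature <= truth.t_b:
        return out
    if truth.t_o is None or temperature <= truth.t_o:
        thermal = temperature - truth.t_b
        margin = psi - psi_b
    else:
        thermal = (
            truth.t_o - truth.t_b
            if truth.supra_thermal == "capped"
            else temperature - truth.t_b
        )
        margin = psi - psi_b - truth.k_T * (temperature - truth.t_o)
    ok = margin > 0
    out[ok] = truth.theta_HT / (thermal * margin[ok])
    return out


def _child_rng(config: SimulationConfig, condition_index: int, replicate_index: int):
    # independent stream per dish, reproducible under any execution order
    return np.random.default_rng(
        [config.rng_seed, condition_index, replicate_index]
    )


def _scoring_days(config: SimulationConfig, times: np.ndarray) -> np.ndarray:
    finite = times[np.isfinite(times)]
    if math.isinf(config.max_days):
        last = float(finite.max()) if finite.size else config.scoring_interval
        n_days = max(1, int(math.ceil(last / config.scoring_interval)))
    else:
        n_days = int(math.floor(config.max_days / config.scoring_interval))
    return config.scoring_interval * np.arange(1, n_days + 1)


def simulate_dish(
    config: SimulationConfig, condition: tuple[float, float], replicate_index: int
) -> GerminationTimeCourse:
    """Simulate one Petri dish under ``condition = (temperature, psi)``.

    Counts accumulate at scoring days (a seed with germination time in
    (d - interval, d] is scored on day d).  Once at least one seed has
    germinated, a run of ``termination_consecutive_zero_days`` scoring days
    with no new germination ends the series (the zero days are recorded, as
    on a bench sheet); dishes where nothing germinates run to ``max_days``.
    """
    temperature, psi = condition
    if condition not in [tuple(c) for c in config.design]:
        raise ValueError(f"condition {condition} not in the configured design")
    rng = _child_rng(config, [tuple(c) for c in config.design].index(condition),
                     replicate_index)
    psi_b = sample_base_potentials(config.truth, config.n_seeds, rng)
    times = latent_times(config.truth, temperature, psi, psi_b)

    days = _scoring_days(config, times)
    cumulative = np.searchsorted(np.sort(times), days, side="right")

    stop = len(days)
    k = config.termination_consecutive_zero_days
    if k is not None:
        increments = np.diff(cumulative, prepend=0)
        run = 0
        started = False
        for i, inc in enumerate(increments):
            started = started or inc > 0
            if not started:
                continue
            run = run + 1 if inc == 0 else 0
            if run >= k:
                stop = i + 1
                break
    return GerminationTimeCourse(
        temperature=temperature,
        water_potential=psi,
        replicate=f"r{replicate_index + 1}",
        n_seeds=config.n_seeds,
        days=days[:stop],
        cumulative=cumulative[:stop],
    )


def simulate_experiment(config: SimulationConfig):
    """Simulate the full factorial: one time course per (condition, replicate).

    Returns ``(timecourses, manifest)``; the manifest records the generating
    truth and all protocol settings so any dataset can be regenerated exactly.
    With ``align_final_day`` every series is padded (constant cumulative
    count) to the latest final scoring day across dishes, for tidy factorial
    tables.
    """
    courses = [
        simulate_dish(config, tuple(cond), rep)
        for cond in config.design
        for rep in range(config.replicates)
    ]
    if config.align_final_day and courses:
        last = max(tc.days[-1] for tc in courses if len(tc))
        aligned = []
        for tc in courses:
            extra = np.round(
                np.arange(tc.days[-1] + config.scoring_interval,
                          last + config.scoring_interval / 2,
                          config.scoring_interval), 10)
            aligned.append(
                GerminationTimeCourse(
                    tc.temperature, tc.water_potential, tc.replicate, tc.n_seeds,
                    np.concatenate([tc.days, extra]),
                    np.concatenate(
                        [tc.cumulative, np.full(extra.size, tc.cumulative[-1])]
                    ),
                )
            )
        courses = aligned
    return courses, config.manifest()
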