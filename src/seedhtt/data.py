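"""Germination time-course containers, CSV I/O and descriptive statistics.

A germination assay scores, for each Petri dish, the cumulative number of
seeds with a protruded radicle at successive scoring days.  One dish is one
(temperature, water potential, replicate) condition.  The long-format CSV
schema used throughout the package is::

    temperature_C,water_potential_MPa,replicate,day,germinated,n_seeds

where ``germinated`` is either a cumulative count or a per-day increment,
declared by the ``counts`` flag of :func:`read_timecourses` (default
cumulative; bench sheets from protocols that remove germinated seeds after
counting are typically incremental).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "CSV_COLUMNS",
    "GerminationObservation",
    "GerminationTimeCourse",
    "read_timecourses",
    "write_timecourses",
    "germination_rate",
    "time_to_fraction",
    "final_germination_percentage",
    "fgp_table",
]

log = logging.getLogger(__name__)

CSV_COLUMNS = [
    "temperature_C",
    "water_potential_MPa",
    "replicate",
    "day",
    "germinated",
    "n_seeds",
]


@dataclass(frozen=True)
class GerminationObservation:
    """A single scoring of one dish: cumulative germinated count at one day."""

    temperature: float  # degrees Celsius
    water_potential: float  # MPa, non-positive
    replicate: str
    day: float  # days since sowing, > 0
    germinated_cumulative: int
    n_seeds: int

    def __post_init__(self) -> None:
        if self.water_potential > 0:
            raise ValidationError(
                f"water potential must be <= 0 MPa, got {self.water_potential}"
            )
        if self.day <= 0:
            raise ValidationError(f"scoring day must be positive, got {self.day}")
        if not 0 <= self.germinated_cumulative <= self.n_seeds:
            raise ValidationError(
                f"cumulative count {self.germinated_cumulative} outside "
                f"[0, n_seeds={self.n_seeds}]"
            )


@dataclass(eq=False)
class GerminationTimeCourse:
    """Cumulative germination counts over scoring days for one dish.

    ``days`` are strictly increasing positive scoring times; ``cumulative``
    are the matching non-decreasing germinated counts out of ``n_seeds``.
    """

    temperature: float
    water_potential: float
    replicate: str
    n_seeds: int
    days: np.ndarray
    cumulative: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=int)
        if self.days.shape != self.cumulative.shape or self.days.ndim != 1:
            raise ValidationError("days and cumulative must be 1-D and equal length")
        if self.water_potential > 0:
            raise ValidationError(
                f"water potential must be <= 0 MPa, got {self.water_potential}"
            )
        if self.days.size:
            if self.days[0] <= 0:
                raise ValidationError("scoring days must be positive")
            if np.any(np.diff(self.days) <= 0):
                raise ValidationError("scoring days must be strictly increasing")
            if np.any(np.diff(self.cumulative) < 0):
                raise ValidationError("cumulative counts must be non-decreasing")
            if self.cumulative[0] < 0 or self.cumulative[-1] > self.n_seeds:
                raise ValidationError(
                    f"cumulative counts must lie in [0, n_seeds={self.n_seeds}]"
                )

    @property
    def condition(self) -> tuple[float, float, str]:
        return (self.temperature, self.water_potential, self.replicate)

    @property
    def fractions(self) -> np.ndarray:
        """Cumulative germinated fraction at each scoring day, in [0, 1]."""
        return self.cumulative / self.n_seeds

    @property
    def observations(self) -> list[GerminationObservation]:
        return [
            GerminationObservation(
                self.temperature,
                self.water_potential,
                self.replicate,
                float(d),
                int(c),
                self.n_seeds,
            )
            for d, c in zip(self.days, self.cumulative)
        ]

    def __len__(self) -> int:
        return self.days.size


def read_timecourses(path, counts: str = "cumulative") -> list[GerminationTimeCourse]:
    """Read a long-format germination CSV into a list of time courses.

    Parameters
    ----------
    path:
        CSV file with header ``temperature_C,water_potential_MPa,replicate,
        day,germinated,n_seeds``.
    counts:
        ``"cumulative"`` if the ``germinated`` column already holds running
        totals, ``"increment"`` if it holds newly germinated seeds per scoring
        day (accumulated on read).

    Returns
    -------
    list of :class:`GerminationTimeCourse`, sorted by (temperature, water
    potential descending toward more negative, replicate).
    """
    if counts not in ("cumulative", "increment"):
        raise ValueError(f"counts must be 'cumulative' or 'increment', got {counts!r}")
    df = pd.read_csv(path)
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    if df.empty:
        log.warning("germination file %s contains a header but no rows", path)
        return []

    courses: list[GerminationTimeCourse] = []
    keys = ["temperature_C", "water_potential_MPa", "replicate"]
    for (temp, psi, rep), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("day")
        n_seeds = int(grp["n_seeds"].iloc[0])
        if not (grp["n_seeds"] == n_seeds).all():
            raise ValidationError(
                f"n_seeds varies within dish (T={temp}, psi={psi}, rep={rep})"
            )
        counts_col = grp["germinated"].to_numpy()
        if counts == "increment":
            if np.any(counts_col < 0):
                row = grp.index[np.argmax(counts_col < 0)]
                raise ValidationError(f"negative increment at input row {row}")
            cum = np.cumsum(counts_col)
        else:
            cum = counts_col
            if np.any(np.diff(cum) < 0):
                row = grp.index[1:][np.diff(cum) < 0][0]
                raise ValidationError(
                    f"cumulative count decreases at input row {row} "
                    f"(T={temp}, psi={psi}, rep={rep})"
                )
        if np.any(cum > n_seeds):
            row = grp.index[np.argmax(cum > n_seeds)]
            raise ValidationError(
                f"germinated count exceeds n_seeds={n_seeds} at input row {row}"
            )
        courses.append(
            GerminationTimeCourse(
                temperature=float(temp),
                water_potential=float(psi),
                replicate=str(rep),
                n_seeds=n_seeds,
                days=grp["day"].to_numpy(dtype=float),
                cumulative=cum,
            )
        )
    return courses


def write_timecourses(courses, path, counts: str = "cumulative") -> None:
    """Write time courses back to the long-format CSV schema (round-trips)."""
    if counts not in ("cumulative", "increment"):
        raise ValueError(f"counts must be 'cumulative' or 'increment', got {counts!r}")
    rows = []
    for tc in courses:
        germ = tc.cumulative
        if counts == "increment":
            germ = np.diff(germ, prepend=0)
        for d, c in zip(tc.days, germ):
            rows.append(
                {
                    "temperature_C": tc.temperature,
                    "water_potential_MPa": tc.water_potential,
                    "replicate": tc.replicate,
                    "day": d,
                    "germinated": int(c),
                    "n_seeds": tc.n_seeds,
                }
            )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def germination_rate(t_g):
    """Germination rate GR_g = 1 / t_g (per day) for time-to-percentile t_g > 0."""
    t_g = np.asarray(t_g, dtype=float)
    if np.any(t_g <= 0):
        raise ValueError("t_g must be positive")
    out = 1.0 / t_g
    return float(out) if out.ndim == 0 else out


def time_to_fraction(tc: GerminationTimeCourse, g: float):
    """Interpolated day at which the cumulative fraction first reaches ``g``.

    Piecewise-linear interpolation on cumulative fraction vs day, with an
    implicit (day 0, fraction 0) sowing point.  Returns ``None`` when the
    final fraction never reaches ``g``.
    """
    if not 0 < g < 1:
        raise ValueError(f"g must be in (0, 1), got {g}")
    if len(tc) == 0:
        raise ValueError("empty time course")
    days = np.concatenate([[0.0], tc.days])
    fracs = np.concatenate([[0.0], tc.fractions])
    if fracs[-1] < g:
        return None
    idx = int(np.searchsorted(fracs, g, side="left"))
    if fracs[idx] == g:
        # first day attaining g exactly
        return float(days[idx])
    lo, hi = idx - 1, idx
    return float(
        days[lo] + (g - fracs[lo]) * (days[hi] - days[lo]) / (fracs[hi] - fracs[lo])
    )


def final_germination_percentage(tc: GerminationTimeCourse) -> float:
    """FGP: 100 x the last cumulative fraction of the time course."""
    if len(tc) == 0:
        raise ValueError("empty time course")
    return 100.0 * float(tc.fractions[-1])


def fgp_table(courses) -> pd.DataFrame:
    """Mean and standard error of FGP per (temperature, water potential).

    The SE is over replicates, matching how factorial germination assays are
    conventionally summarised.
    """
    rows = [
        {
            "temperature_C": tc.temperature,
            "water_potential_MPa": tc.water_potential,
            "fgp": final_germination_percentage(tc),
        }
        for tc in courses
    ]
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["temperature_C", "water_potential_MPa"])["fgp"]
        .agg(mean_fgp="mean", se_fgp=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n_reps="count")
        .reset_index()
    )
    return out
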