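"""Prior migration phenology model.

Migration presence is modelled with a six-parameter curve per species:

    m(lat, day) = min{ Phi[(day - mu_S(lat)) / sigma_S],
                       1 - Phi[(day - mu_A(lat)) / sigma_A] }

where mu_S(lat) = theta_SM + theta_SL * lat is the mean spring arrival day at a
latitude, sigma_S the spread of arrival, and (mu_A, sigma_A) the analogous
autumn departure terms.  Non-migratory species have m = 1 everywhere.

The prior parameters are fitted from long-term occurrence data: per year and
latitude zone, the "first" and "last" observation days are the 5%/95%
accumulation quantiles (groups with fewer than 50 occurrences are dropped);
first days are regressed on latitude by OLS to give the spring mean/slope (and
last days the autumn ones), while the spread parameters are one fourth of the
95% prediction-interval width, averaged over zones, floored at 0.5 days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import std_normal_cdf
from .prior_detection import FitError

__all__ = [
    "MigrationParams",
    "PhenologySummary",
    "migration_probability",
    "quantile_first_last",
    "fit_prior_migration",
    "read_migration_table",
    "write_migration_table",
]

logger = logging.getLogger(__name__)

SD_FLOOR_DAYS = 0.5


@dataclass(frozen=True)
class MigrationParams:
    """Six-parameter phenology curve; spread parameters are floored at 0.5 days."""

    spring_mean: float = 0.0
    spring_lat_slope: float = 0.0
    spring_sd: float = SD_FLOOR_DAYS
    autumn_mean: float = 0.0
    autumn_lat_slope: float = 0.0
    autumn_sd: float = SD_FLOOR_DAYS
    is_migratory: bool = True

    def __post_init__(self) -> None:
        if self.is_migratory and (self.spring_sd <= 0 or self.autumn_sd <= 0):
            raise ValueError("spread parameters must be positive for migratory species")

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.spring_mean,
                self.spring_lat_slope,
                self.spring_sd,
                self.autumn_mean,
                self.autumn_lat_slope,
                self.autumn_sd,
            ],
            dtype=float,
        )


@dataclass(frozen=True)
class PhenologySummary:
    """First/last observation-day quantiles for one year x latitude zone."""

    year: int
    zone_latitude_deg: float
    first_day: int
    last_day: int
    n_observations: int

    def __post_init__(self) -> None:
        if self.n_observations < 50:
            raise ValueError("summaries require at least 50 observations")
        if self.first_day > self.last_day:
            raise ValueError("first_day must not exceed last_day")


def migration_probability(params: MigrationParams, latitude_deg, day_of_year):
    """Probability the species has arrived and not departed; 1 for residents."""
    lat = np.asarray(latitude_deg, dtype=float)
    day = np.asarray(day_of_year, dtype=float)
    if not params.is_migratory:
        out = np.ones(np.broadcast_shapes(lat.shape, day.shape))
        return float(out) if out.ndim == 0 else out
    spring = std_normal_cdf((day - (params.spring_mean + params.spring_lat_slope * lat)) / params.spring_sd)
    autumn = 1.0 - std_normal_cdf((day - (params.autumn_mean + params.autumn_lat_slope * lat)) / params.autumn_sd)
    out = np.minimum(spring, autumn)
    return float(out) if np.ndim(out) == 0 else out


def quantile_first_last(
    observation_days: Mapping[tuple[int, float], Sequence[int]],
) -> list[PhenologySummary]:
    """Per year-zone first/last day order statistics (ceil(q n)-th, q = 5%/95%).

    ``observation_days`` maps (year, zone_latitude) to the observation days of
    that group; groups with fewer than 50 observations are dropped (counted in
    a log message).
    """
    rows: list[PhenologySummary] = []
    n_dropped = 0
    for (year, lat), days in observation_days.items():
        days_sorted = np.sort(np.asarray(days, dtype=int))
        n = days_sorted.size
        if n < 50:
            n_dropped += 1
            continue
        lo = int(np.ceil(0.05 * n)) - 1
        hi = int(np.ceil(0.95 * n)) - 1
        rows.append(
            PhenologySummary(
                year=int(year),
                zone_latitude_deg=float(lat),
                first_day=int(days_sorted[lo]),
                last_day=int(days_sorted[hi]),
                n_observations=int(n),
            )
        )
    if n_dropped:
        logger.info("quantile_first_last dropped %d under-sized year-zone groups", n_dropped)
    return rows


def _ols_with_band(lat: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS of y on latitude; returns (intercept, slope, spread).

    The spread is one fourth of the 95% OLS prediction-interval width averaged
    over the distinct zone latitudes, floored at 0.5 days.
    """
    X = sm.add_constant(lat)
    res = sm.OLS(y, X).fit()
    zones = np.unique(lat)
    pred = res.get_prediction(sm.add_constant(zones))
    frame = pred.summary_frame(alpha=0.05)
    width = (frame["obs_ci_upper"] - frame["obs_ci_lower"]).to_numpy()
    spread = max(float(np.mean(width)) / 4.0, SD_FLOOR_DAYS)
    if not np.isfinite(spread):
        spread = SD_FLOOR_DAYS
    return float(res.params[0]), float(res.params[1]), spread


def fit_prior_migration(summaries: Sequence[PhenologySummary]) -> MigrationParams:
    """Fit the six phenology parameters from year-zone first/last summaries."""
    if len(summaries) < 2:
        raise FitError("need at least two summaries")
    lat = np.array([s.zone_latitude_deg for s in summaries], dtype=float)
    if np.unique(lat).size < 2:
        raise FitError("need at least two distinct latitude zones")
    first = np.array([s.first_day for s in summaries], dtype=float)
    last = np.array([s.last_day for s in summaries], dtype=float)
    s_mean, s_slope, s_sd = _ols_with_band(lat, first)
    a_mean, a_slope, a_sd = _ols_with_band(lat, last)
    return MigrationParams(
        spring_mean=s_mean,
        spring_lat_slope=s_slope,
        spring_sd=s_sd,
        autumn_mean=a_mean,
        autumn_lat_slope=a_slope,
        autumn_sd=a_sd,
        is_migratory=True,
    )


# --- parameter table I/O ---------------------------------------------------

_COLS = ["species_id", "is_migratory", "s_mean", "s_lat", "s_sd", "a_mean", "a_lat", "a_sd"]


def write_migration_table(params: Mapping[str, MigrationParams], path: str | Path) -> None:
    rows = []
    for sp, p in params.items():
        rows.append(
            {
                "species_id": sp,
                "is_migratory": p.is_migratory,
                "s_mean": p.spring_mean,
                "s_lat": p.spring_lat_slope,
                "s_sd": p.spring_sd,
                "a_mean": p.autumn_mean,
                "a_lat": p.autumn_lat_slope,
                "a_sd": p.autumn_sd,
            }
        )
    pd.DataFrame(rows, columns=_COLS).to_csv(path, index=False)


def read_migration_table(path: str | Path) -> dict[str, MigrationParams]:
    frame = pd.read_csv(path)
    out = {}
    for _, r in frame.iterrows():
        out[str(r["species_id"])] = MigrationParams(
            spring_mean=float(r["s_mean"]),
            spring_lat_slope=float(r["s_lat"]),
            spring_sd=float(r["s_sd"]),
            autumn_mean=float(r["a_mean"]),
            autumn_lat_slope=float(r["a_lat"]),
            autumn_sd=float(r["a_sd"]),
            is_migratory=bool(r["is_migratory"]),
        )
    return out
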