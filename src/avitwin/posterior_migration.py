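"""Year-specific MAP update of migration parameters under a functional prior.

Within a year, migration timing can deviate from the long-term average the
prior captures.  The posterior parameters minimize the Bernoulli deviance of
the season's app detections (with the spatial and detection components fixed)
plus lambda times a functional penalty: the integrated squared difference
between the posterior and prior migration curves over a (latitude, day) grid.
Penalizing the *curve* rather than raw parameters allows large parameter moves
that barely change the curve (e.g. step-like arrivals) while keeping its shape
stable.  Parameters reset to the prior every 1 January; only the current
year's records enter the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .prior_detection import FitError
from .prior_migration import SD_FLOOR_DAYS, MigrationParams, migration_probability

__all__ = [
    "PenaltyGrid",
    "MigrationUpdateConfig",
    "functional_penalty",
    "fit_posterior_migration",
]


@dataclass(frozen=True)
class PenaltyGrid:
    """Uniform (latitude, day) grid over which the penalty integral is summed."""

    latitudes_deg: tuple[float, ...]
    days: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.latitudes_deg or not self.days:
            raise ValueError("penalty grid must be non-empty")
        for axis in (self.latitudes_deg, self.days):
            arr = np.asarray(axis, dtype=float)
            if arr.size > 1:
                steps = np.diff(arr)
                if (steps <= 0).any() or not np.allclose(steps, steps[0]):
                    raise ValueError("grid axes must be ascending and uniformly spaced")

    @classmethod
    def default(cls) -> "PenaltyGrid":
        """Latitudes 59.5..70.0 step 0.5 deg; days 1..365 step 1."""
        return cls(tuple(np.arange(59.5, 70.01, 0.5)), tuple(range(1, 366)))

    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        lat = np.asarray(self.latitudes_deg, dtype=float)
        day = np.asarray(self.days, dtype=float)
        return np.meshgrid(lat, day, indexing="ij")

    @property
    def domain_area(self) -> float:
        """Product of axis extents (degree x days); a degenerate axis counts 1."""
        lat = np.asarray(self.latitudes_deg, dtype=float)
        day = np.asarray(self.days, dtype=float)
        lat_range = lat[-1] - lat[0] if lat.size > 1 else 1.0
        day_range = day[-1] - day[0] if day.size > 1 else 1.0
        return float(lat_range * day_range)


@dataclass(frozen=True)
class MigrationUpdateConfig:
    lambda_precision: float = 0.01
    grid: PenaltyGrid = field(default_factory=PenaltyGrid.default)

    def __post_init__(self) -> None:
        if self.lambda_precision <= 0:
            raise ValueError("lambda_precision must be positive")


def functional_penalty(
    theta_tilde: MigrationParams, theta_prior: MigrationParams, grid: PenaltyGrid
) -> float:
    """Riemann approximation of the integrated squared curve difference.

    Mean of [m_tilde - m_prior]^2 over the grid times the domain area, i.e.
    the midpoint-rule value of the double integral in degree*day units.
    """
    lat, day = grid.mesh()
    diff = migration_probability(theta_tilde, lat, day) - migration_probability(theta_prior, lat, day)
    return float(np.mean(diff**2) * grid.domain_area)


def _unpack(vec: np.ndarray) -> MigrationParams:
    return MigrationParams(
        spring_mean=float(vec[0]),
        spring_lat_slope=float(vec[1]),
        spring_sd=float(max(np.exp(vec[2]), SD_FLOOR_DAYS / 10)),
        autumn_mean=float(vec[3]),
        autumn_lat_slope=float(vec[4]),
        autumn_sd=float(max(np.exp(vec[5]), SD_FLOOR_DAYS / 10)),
        is_migratory=True,
    )


def _pack(p: MigrationParams) -> np.ndarray:
    return np.array(
        [
            p.spring_mean,
            p.spring_lat_slope,
            np.log(p.spring_sd),
            p.autumn_mean,
            p.autumn_lat_slope,
            np.log(p.autumn_sd),
        ]
    )


def fit_posterior_migration(
    y,
    latitude_deg,
    day_of_year,
    sd_fixed,
    theta_prior: MigrationParams,
    config: MigrationUpdateConfig | None = None,
) -> MigrationParams:
    """MAP update of the migration parameters from one season's records.

    Per-recording arrays: binary detections ``y``, latitudes, days of year and
    the fixed product ``sd_fixed`` = spatial probability x detection
    probability.  Minimizes the Bernoulli deviance with success probability
    m(theta; lat, day) * sd_fixed plus lambda * functional_penalty, starting
    from the prior; the spread parameters are optimized on the log scale to
    stay positive.  With zero records the prior is returned exactly; the
    ``is_migratory`` flag is never changed (residents have a constant curve,
    so there is nothing to update).
    """
    if config is None:
        config = MigrationUpdateConfig()
    y = np.asarray(y, dtype=float)
    if y.size == 0 or not theta_prior.is_migratory:
        return theta_prior
    lat = np.asarray(latitude_deg, dtype=float)
    day = np.asarray(day_of_year, dtype=float)
    sd = np.asarray(sd_fixed, dtype=float)
    years_span = day.max() - day.min()
    if years_span > 366:
        raise ValueError("records must come from a single calendar year")
    lam = config.lambda_precision
    grid_lat, grid_day = config.grid.mesh()
    area = config.grid.domain_area
    prior_curve = migration_probability(theta_prior, grid_lat, grid_day)

    def objective(vec: np.ndarray) -> float:
        theta = _unpack(vec)
        m = migration_probability(theta, lat, day)
        p = np.clip(m * sd, 1e-12, 1 - 1e-12)
        nll = -(y * np.log(p) + (1 - y) * np.log1p(-p)).sum()
        diff = migration_probability(theta, grid_lat, grid_day) - prior_curve
        return float(nll + lam * np.mean(diff**2) * area)

    x0 = _pack(theta_prior)
    # box constraints keep the optimizer in the numerically sane region: the
    # intercept/slope trade-off stays essentially free (a degree of latitude
    # spans few days), while the spread parameters cannot run away
    log_sd_lo, log_sd_hi = np.log(SD_FLOOR_DAYS), np.log(90.0)
    bounds = [
        (x0[0] - 400, x0[0] + 400),
        (x0[1] - 6, x0[1] + 6),
        (log_sd_lo, log_sd_hi),
        (x0[3] - 400, x0[3] + 400),
        (x0[4] - 6, x0[4] + 6),
        (log_sd_lo, log_sd_hi),
    ]
    x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
    res = minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": 500, "ftol": 1e-12}
    )
    best = res.x if objective(res.x) <= objective(x0) else x0
    if not np.isfinite(objective(best)):
        raise FitError(f"posterior migration fit diverged: {res.message}")
    fitted = _unpack(best)
    if fitted.spring_sd < SD_FLOOR_DAYS or fitted.autumn_sd < SD_FLOOR_DAYS:
        fitted = MigrationParams(
            spring_mean=fitted.spring_mean,
            spring_lat_slope=fitted.spring_lat_slope,
            spring_sd=max(fitted.spring_sd, SD_FLOOR_DAYS),
            autumn_mean=fitted.autumn_mean,
            autumn_lat_slope=fitted.autumn_lat_slope,
            autumn_sd=max(fitted.autumn_sd, SD_FLOOR_DAYS),
            is_migratory=True,
        )
    return fitted
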