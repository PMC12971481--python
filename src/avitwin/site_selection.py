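"""Utility-driven sequential selection of validation survey sites.

Validation point counts are most informative where the prior and posterior
occurrence maps disagree.  For species j at candidate cell c the base utility
is f_j(c) = |posterior - prior|; repeat sampling of the same prior/posterior
"scenario" is discouraged by a penalty product over previously chosen sites,

    U_j(c | history) = f_j(c) * prod_i (1 - g_j(c, c_i)),
    g_j(c, c_i) = gamma * 1(m_j at c_i >= 0.75)
                  * exp(-(tau/2) * [(dprior)^2 + (dposterior)^2]),

a Gaussian kernel in probability space (tau = 400 corresponds to a 0.05 sd)
scaled by gamma = 0.95 so the utility never hits exactly zero; the migration
indicator voids the penalty for chosen sites the species had not yet reached.
The day's total utility sums migration-gated species utilities, and sites are
picked greedily under hierarchical distance constraints: the first site within
50 km of the volunteer's home, the rest within 10 km of the first, all at
least 1 km from every previously selected site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import CellIndex, GridSpec, cell_distance_km

__all__ = [
    "SelectionConfig",
    "ChosenSite",
    "SelectionState",
    "disagreement_term",
    "scenario_penalty",
    "species_utility",
    "total_utility",
    "select_day_sites",
    "point_count_layout",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    gamma: float = 0.95
    tau_scenario: float = 400.0
    migration_threshold: float = 0.75
    central_radius_km: float = 50.0
    satellite_radius_km: float = 10.0
    min_separation_km: float = 1.0
    sites_per_volunteer: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must lie in (0, 1)")
        if self.tau_scenario <= 0:
            raise ValueError("tau_scenario must be positive")


@dataclass(frozen=True)
class ChosenSite:
    """One selected site with its per-species scenario cached at selection time."""

    cell: CellIndex
    day: int
    prior: tuple[float, ...]
    posterior: tuple[float, ...]
    migration: tuple[float, ...]  # m_j at this cell on its selection day


@dataclass
class SelectionState:
    """Chronologically ordered history of chosen sites across the campaign."""

    chosen: list[ChosenSite] = field(default_factory=list)

    def add(self, site: ChosenSite) -> None:
        if self.chosen and site.day < self.chosen[-1].day:
            raise ValueError("sites must be added in chronological order")
        if any(s.cell == site.cell and s.day == site.day for s in self.chosen):
            raise ValueError("duplicate site for the same day")
        self.chosen.append(site)


def disagreement_term(prior_prob: float, posterior_prob: float) -> float:
    """|posterior - prior|: direction-agnostic prior/posterior disagreement."""
    if not (0 <= prior_prob <= 1 and 0 <= posterior_prob <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return abs(posterior_prob - prior_prob)


def scenario_penalty(
    cand_prior: float,
    cand_posterior: float,
    chosen_prior: float,
    chosen_posterior: float,
    migration_prob_at_chosen: float,
    config: SelectionConfig | None = None,
) -> float:
    """Penalty kernel g for one (candidate, previously chosen site) pair.

    gamma * indicator(migration at the chosen site >= threshold) *
    exp(-(tau/2) * [(dprior)^2 + (dposterior)^2]), in [0, gamma].
    """
    if config is None:
        config = SelectionConfig()
    if migration_prob_at_chosen < config.migration_threshold:
        return 0.0
    dq = (cand_prior - chosen_prior) ** 2 + (cand_posterior - chosen_posterior) ** 2
    return config.gamma * float(np.exp(-config.tau_scenario / 2.0 * dq))


def species_utility(
    cand_prior: float,
    cand_posterior: float,
    state: SelectionState,
    species_index: int,
    config: SelectionConfig | None = None,
) -> float:
    """U_j = f_j(candidate) * prod over history of (1 - g_j); f_j if no history."""
    if config is None:
        config = SelectionConfig()
    u = disagreement_term(cand_prior, cand_posterior)
    for site in state.chosen:
        g = scenario_penalty(
            cand_prior,
            cand_posterior,
            site.prior[species_index],
            site.posterior[species_index],
            site.migration[species_index],
            config,
        )
        u *= 1.0 - g
    return u


def total_utility(
    cand_prior,
    cand_posterior,
    cand_migration,
    state: SelectionState,
    config: SelectionConfig | None = None,
) -> float:
    """Sum over species of the migration-gated utility at the candidate cell.

    ``cand_migration`` holds m_j at the candidate cell on the selection day;
    species below the migration threshold there contribute zero.
    """
    if config is None:
        config = SelectionConfig()
    cand_prior = np.asarray(cand_prior, dtype=float)
    cand_posterior = np.asarray(cand_posterior, dtype=float)
    cand_migration = np.asarray(cand_migration, dtype=float)
    total = 0.0
    for j in range(cand_prior.size):
        if cand_migration[j] < config.migration_threshold:
            continue
        total += species_utility(cand_prior[j], cand_posterior[j], state, j, config)
    return total


def select_day_sites(
    volunteer_home: CellIndex,
    candidates: list[CellIndex],
    prior: np.ndarray,
    posterior: np.ndarray,
    migration: np.ndarray,
    state: SelectionState,
    grid: GridSpec,
    day: int,
    config: SelectionConfig | None = None,
) -> list[tuple[CellIndex, float]]:
    """Greedy selection of one volunteer's sites for one day.

    ``prior``/``posterior``/``migration`` are (n_candidates, n_species) arrays
    aligned with ``candidates``.  The first site maximizes total utility within
    the central radius of home; subsequent sites maximize it within the
    satellite radius of the first site.  Every pick must be at least the
    minimum separation from all previously selected sites (current and past
    days); the state is updated after each pick, so same-day picks penalize
    each other.  Ties break on (utility, row, col), lower (row, col) winning.
    Returns (cell, utility) pairs; fewer than the configured number with a
    logged warning when the pool is exhausted.
    """
    if config is None:
        config = SelectionConfig()
    prior = np.asarray(prior, dtype=float)
    posterior = np.asarray(posterior, dtype=float)
    migration = np.asarray(migration, dtype=float)

    def admissible(cell: CellIndex, center: CellIndex, radius: float) -> bool:
        if cell_distance_km(cell, center, grid) > radius:
            return False
        return all(
            cell_distance_km(cell, s.cell, grid) >= config.min_separation_km for s in state.chosen
        )

    picks: list[tuple[CellIndex, float]] = []
    center, radius = volunteer_home, config.central_radius_km
    for rank in range(config.sites_per_volunteer):
        best: tuple[float, int, int] | None = None
        best_idx = -1
        for idx, cell in enumerate(candidates):
            if not admissible(cell, center, radius):
                continue
            u = total_utility(prior[idx], posterior[idx], migration[idx], state, config)
            key = (-u, cell.row, cell.col)
            if best is None or key < best:
                best, best_idx = key, idx
        if best is None:
            logger.warning("site selection pool exhausted after %d of %d picks", rank, config.sites_per_volunteer)
            break
        cell = candidates[best_idx]
        util = -best[0]
        picks.append((cell, util))
        state.add(
            ChosenSite(
                cell=cell,
                day=day,
                prior=tuple(prior[best_idx]),
                posterior=tuple(posterior[best_idx]),
                migration=tuple(migration[best_idx]),
            )
        )
        if rank == 0:
            center, radius = cell, config.satellite_radius_km
    return picks


def point_count_layout(center_easting_km: float, center_northing_km: float) -> list[tuple[float, float]]:
    """Center plus the four corners of the axis-aligned 100 m square at a site."""
    h = 0.05  # km
    return [
        (center_easting_km, center_northing_km),
        (center_easting_km - h, center_northing_km - h),
        (center_easting_km - h, center_northing_km + h),
        (center_easting_km + h, center_northing_km - h),
        (center_easting_km + h, center_northing_km + h),
    ]
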