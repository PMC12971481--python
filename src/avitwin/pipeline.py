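"""Orchestration: twin state, nightly updates and end-to-end synthetic evaluation.

The twin is updated statelessly: each nightly update refits the year-specific
migration parameters and the spatial posterior from the *cumulative*
season-to-date stream rather than incrementally from yesterday's posterior, so
two consecutive daily updates produce exactly the same state as one update
with the concatenated data.  The detection translation is refitted only at
year boundaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .core import DetectionMatrix, GridSpec, RasterLayer, day_fraction, minute_fraction
from .evaluation import SpeciesPriorBundle, WalkForwardConfig, walk_forward
from .posterior_detection import TranslationParams, d_mk, fit_translation
from .posterior_migration import MigrationUpdateConfig, PenaltyGrid, fit_posterior_migration
from .posterior_spatial import SpatialUpdateConfig, update_raster, upsample_raster
from .prior_detection import FitError, predict_d_pam
from .prior_migration import MigrationParams, migration_probability
from .synthetic import ObserverPopulation, SyntheticWorld, make_world, perturb_prior, simulate_mk_stream
from .core import CellIndex

__all__ = [
    "TwinState",
    "RunConfig",
    "run_daily_update",
    "fit_translations_from_stream",
    "run_evaluation",
]

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Validated configuration of a synthetic simulate+update+evaluate run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n_species: int = 10
    n_rows: int = 200
    n_cols: int = 200
    n_users: int = 200
    spatial_shift_sd: float = 1.2
    migration_shift_days: float = 10.0
    prior_sd_const: float = 0.15
    burnin_year: int = 2023
    eval_year: int = 2024
    season_start_day: int = 113
    season_end_day: int = 162
    forecast_window_days: int = 7
    min_detections_per_species: int = 100
    lambda_precision: float = 0.01
    tau_spatial: float = 1.0 / 2.5**2
    truncation_radius_km: float = 7.5
    penalty_lat_step: float = 0.5
    penalty_day_step: int = 2

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def spatial_config(self) -> SpatialUpdateConfig:
        return SpatialUpdateConfig(
            tau_spatial=self.tau_spatial, truncation_radius_km=self.truncation_radius_km
        )

    def migration_config(self, lat_lo: float = 59.5, lat_hi: float = 70.0) -> MigrationUpdateConfig:
        grid = PenaltyGrid(
            tuple(np.arange(lat_lo, lat_hi + 1e-9, self.penalty_lat_step)),
            tuple(range(1, 366, self.penalty_day_step)),
        )
        return MigrationUpdateConfig(lambda_precision=self.lambda_precision, grid=grid)


@dataclass
class TwinState:
    """Snapshot of the twin after the nightly update for ``as_of_day``."""

    as_of_day: int
    year: int
    fine_grid: GridSpec
    stream: DetectionMatrix  # cumulative current-year records
    priors: dict[str, SpeciesPriorBundle]
    migration_post: dict[str, MigrationParams] = field(default_factory=dict)
    spatial_post_coarse: dict[str, RasterLayer] = field(default_factory=dict)
    spatial_post_sd: dict[str, RasterLayer] = field(default_factory=dict)
    spatial_post_fine: dict[str, RasterLayer] = field(default_factory=dict)
    config_hash: str = ""
    seed: int = 0


def _species_arrays(stream: DetectionMatrix, bundle: SpeciesPriorBundle, fine_grid: GridSpec):
    meta = stream.meta_frame()
    day = meta["day_of_year"].to_numpy()
    lat = meta["latitude_deg"].to_numpy()
    dpam = predict_d_pam(
        bundle.detection, day_fraction(day), minute_fraction(meta["minute_of_day"].to_numpy())
    )
    dmk = d_mk(bundle.translation, meta["rec_type"].cat.codes.to_numpy(), meta["log_duration"].to_numpy(), dpam)
    fr, fc = meta["row"].to_numpy(), meta["col"].to_numpy()
    factor = round(bundle.coarse_mean.grid.cell_size_km / fine_grid.cell_size_km)
    return day, lat, dpam, dmk, fr, fc, fr // factor, fc // factor


def run_daily_update(
    state: TwinState,
    new_records: DetectionMatrix,
    spatial_config: SpatialUpdateConfig | None = None,
    migration_config: MigrationUpdateConfig | None = None,
) -> TwinState:
    """Advance the twin by one day with the latest batch of recordings.

    The batch may contain records dated up to ``state.as_of_day + 1``; any
    later record is a hard failure.  Species without a prior bundle are
    skipped with a log entry.  The returned state is identical to refitting
    from scratch on the concatenated cumulative data.
    """
    new_day = state.as_of_day + 1
    if len(new_records):
        batch_days = new_records.meta_frame()["day_of_year"].to_numpy()
        batch_years = new_records.meta_frame()["year"].to_numpy()
        if (batch_years > state.year).any() or (
            (batch_years == state.year) & (batch_days > new_day)
        ).any():
            raise ValueError(f"batch contains records dated after day {new_day}")
        if new_records.species_ids != state.stream.species_ids and len(state.stream):
            raise ValueError("batch species must match the cumulative stream")
    if len(state.stream) and len(new_records):
        stream = DetectionMatrix(
            recordings=state.stream.recordings + new_records.recordings,
            species_ids=state.stream.species_ids,
            values=np.vstack([state.stream.values, new_records.values]),
        )
    elif len(new_records):
        stream = new_records
    else:
        stream = state.stream
    if spatial_config is None:
        spatial_config = SpatialUpdateConfig()
    if migration_config is None:
        migration_config = MigrationUpdateConfig()

    migration_post: dict[str, MigrationParams] = {}
    coarse: dict[str, RasterLayer] = {}
    coarse_sd: dict[str, RasterLayer] = {}
    fine: dict[str, RasterLayer] = {}
    for sp in stream.species_ids:
        if sp not in state.priors:
            logger.info("species %s skipped in daily update: missing priors", sp)
            continue
        bundle = state.priors[sp]
        y = stream.species_column(sp).astype(float)
        day, lat, _, dmk, fr, fc, cr, cc = _species_arrays(stream, bundle, state.fine_grid)
        s_prior = bundle.fine_mean.values[fr, fc]
        theta = fit_posterior_migration(
            y, lat, day, np.clip(s_prior * dmk, 1e-12, 1 - 1e-12), bundle.migration, migration_config
        )
        m_post = migration_probability(theta, lat, day)
        post_c, post_sd = update_raster(
            y,
            np.clip(m_post * dmk, 1e-12, 1 - 1e-12),
            cr,
            cc,
            bundle.coarse_mean,
            bundle.coarse_sd,
            spatial_config,
        )
        migration_post[sp] = theta
        coarse[sp] = post_c
        coarse_sd[sp] = post_sd
        fine[sp] = upsample_raster(post_c, bundle.fine_mean)
    return replace(
        state,
        as_of_day=new_day,
        stream=stream,
        migration_post=migration_post,
        spatial_post_coarse=coarse,
        spatial_post_sd=coarse_sd,
        spatial_post_fine=fine,
    )


def fit_translations_from_stream(
    stream: DetectionMatrix,
    priors: Mapping[str, SpeciesPriorBundle],
    fine_grid: GridSpec,
    fit_year: int,
) -> dict[str, SpeciesPriorBundle]:
    """Annual translation refit on a (burn-in) stream; returns updated bundles.

    Species whose stream slice is single-class keep their existing translation
    and are reported in the log.
    """
    meta = stream.meta_frame()
    day = meta["day_of_year"].to_numpy()
    minute = meta["minute_of_day"].to_numpy()
    lat = meta["latitude_deg"].to_numpy()
    fr, fc = meta["row"].to_numpy(), meta["col"].to_numpy()
    rec_codes = meta["rec_type"].cat.codes.to_numpy()
    logdur = meta["log_duration"].to_numpy()
    out: dict[str, SpeciesPriorBundle] = {}
    for sp, bundle in priors.items():
        if sp not in stream.species_ids:
            out[sp] = bundle
            continue
        y = stream.species_column(sp).astype(float)
        dpam = predict_d_pam(bundle.detection, day_fraction(day), minute_fraction(minute))
        m = migration_probability(bundle.migration, lat, day)
        s = bundle.fine_mean.values[fr, fc]
        try:
            trans = fit_translation(y, rec_codes, logdur, dpam, np.clip(m * s, 1e-12, 1 - 1e-12))
        except FitError as exc:
            logger.warning("translation fit skipped for %s (%d): %s", sp, fit_year, exc)
            out[sp] = bundle
            continue
        out[sp] = replace(bundle, translation=trans)
    return out


def run_evaluation(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Full synthetic cycle: world -> priors -> burn-in -> walk-forward AUCs.

    Simulates a ground-truth world and a perturbed prior, fits the detection
    translation on a burn-in season (the year before evaluation), runs the
    walk-forward next-window evaluation on the evaluation-year stream, and
    writes ``results.csv`` plus a JSON sidecar with the config hash and seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(5) % (2**31)
    world = make_world(
        n_species=config.n_species,
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        seed=int(seeds[0]),
    )
    priors = perturb_prior(
        world,
        spatial_shift_sd=config.spatial_shift_sd,
        migration_shift_days=config.migration_shift_days,
        prior_sd_const=config.prior_sd_const,
        seed=int(seeds[1]),
    )
    rng = np.random.default_rng(int(seeds[2]))
    homes = tuple(
        CellIndex(int(r), int(c))
        for r, c in zip(
            rng.integers(0, config.n_rows, config.n_users),
            rng.integers(0, config.n_cols, config.n_users),
        )
    )
    stations = tuple(
        CellIndex(int(r), int(c))
        for r, c in zip(rng.integers(0, config.n_rows, 12), rng.integers(0, config.n_cols, 12))
    )
    observers = ObserverPopulation(home_cells=homes, point_station_cells=stations)
    days = range(config.season_start_day, config.season_end_day + config.forecast_window_days + 1)
    burnin = simulate_mk_stream(world, observers, days, year=config.burnin_year, seed=int(seeds[3]))
    priors = fit_translations_from_stream(burnin, priors, world.grid, config.burnin_year)
    stream = simulate_mk_stream(world, observers, days, year=config.eval_year, seed=int(seeds[4]))
    wf_config = WalkForwardConfig(
        start_day=config.season_start_day,
        end_day=config.season_end_day,
        forecast_window_days=config.forecast_window_days,
        min_detections_per_species=config.min_detections_per_species,
    )
    results = walk_forward(
        stream,
        world.grid,
        priors,
        wf_config,
        config.spatial_config(),
        config.migration_config(world.lat_south_deg - 0.5, world.lat_north_deg + 0.5),
    )
    results.to_csv(out_dir / "results.csv", index=False)
    sidecar = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_recordings_eval": len(stream),
        "n_recordings_burnin": len(burnin),
    }
    (out_dir / "run_meta.json").write_text(json.dumps(sidecar, indent=2))
    return results
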