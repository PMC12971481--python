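"""Synthetic worlds with known ground truth.

Generates desk-scale stand-ins for the real system: a fine 200x200 grid of
1-ha cells mapped to latitudes 60-62, species with known migration phenology,
periodic vocal-activity curves, true spatial occurrence fields and true
app-translation parameters; priors that deviate from the truth in a controlled
way; and the two observation streams: 1-minute passive-monitoring segments,
and an app-style stream of direct / interval / point recordings whose
detections are Bernoulli draws from the product model m * s * d.

Every generator is a pure function of its inputs and seed; independent
sub-streams (recording timing vs detection draws) come from spawned seed
sequences so regenerating one leaves the other unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import ndtr, ndtri

from .core import CellIndex, DetectionMatrix, GridSpec, RasterLayer, RecordingMeta, Timestamp
from .evaluation import SpeciesPriorBundle
from .posterior_detection import TranslationParams, d_mk
from .posterior_spatial import downsample_prior
from .prior_detection import DetectionCoefficients, PamRecord, predict_d_pam
from .prior_migration import MigrationParams, migration_probability
from .core import day_fraction, minute_fraction

__all__ = [
    "SpeciesTruth",
    "SyntheticWorld",
    "ObserverPopulation",
    "make_world",
    "perturb_prior",
    "simulate_pam",
    "simulate_mk_stream",
]

# users record between 04:00 and 22:00
_ACTIVE_START, _ACTIVE_END = 240, 1320


@dataclass(frozen=True)
class SpeciesTruth:
    species_id: str
    migration: MigrationParams
    detection: DetectionCoefficients
    translation: TranslationParams
    spatial_field: RasterLayer  # fine-grid true occurrence probability


@dataclass(frozen=True)
class SyntheticWorld:
    grid: GridSpec  # fine grid
    species: tuple[SpeciesTruth, ...]
    lat_north_deg: float
    lat_south_deg: float
    seed: int

    def latitude_of_row(self, row) -> np.ndarray | float:
        """Affine map from fine-grid row (0 = north) to decimal degrees."""
        r = np.asarray(row, dtype=float)
        span = self.lat_north_deg - self.lat_south_deg
        out = self.lat_north_deg - (r + 0.5) / self.grid.n_rows * span
        return float(out) if out.ndim == 0 else out

    @property
    def species_ids(self) -> list[str]:
        return [sp.species_id for sp in self.species]


@dataclass(frozen=True)
class ObserverPopulation:
    """App users: homes on the fine grid, activity rates and recording-type mix."""

    home_cells: tuple[CellIndex, ...]
    direct_rate_per_day: float = 2.0
    trigger_bias: float = 2.0
    type_mix: tuple[float, float, float] = (0.7, 0.15, 0.15)  # direct/interval/point
    point_station_cells: tuple[CellIndex, ...] = ()
    interval_session_prob: float = 0.3
    point_visit_prob: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type mix proportions must sum to 1")


def _smooth_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Band-limited standard-normal surface (unit variance after smoothing)."""
    noise = rng.standard_normal(shape)
    smooth = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    return (smooth - smooth.mean()) / smooth.std()


def make_world(
    n_species: int = 10,
    n_rows: int = 200,
    n_cols: int = 200,
    seed: int = 0,
    migratory_fraction: float = 0.8,
    lat_north_deg: float = 62.0,
    lat_south_deg: float = 60.0,
    field_sigma_cells: float = 40.0,
) -> SyntheticWorld:
    """A reproducible world: smooth true occurrence fields in [0.02, 0.98],
    migration parameters in realistic spring/autumn ranges, per-minute vocal
    detection around a few percent, and app-translation coefficients that make
    longer recordings more detectable."""
    if n_species < 1:
        raise ValueError("n_species must be at least 1")
    rng = np.random.default_rng(seed)
    grid = GridSpec(
        origin_easting_km=0.0,
        origin_northing_km=n_rows * 0.1,
        cell_size_km=0.1,
        n_rows=n_rows,
        n_cols=n_cols,
    )
    species = []
    for k in range(n_species):
        z = _smooth_field(rng, (n_rows, n_cols), field_sigma_cells)
        offset = rng.uniform(-0.8, 0.3)
        vals = np.clip(ndtr(1.2 * z + offset), 0.02, 0.98)
        is_migratory = bool(rng.random() < migratory_fraction)
        arrival60 = rng.uniform(100.0, 140.0)
        s_slope = rng.uniform(0.5, 2.0)
        a_depart60 = rng.uniform(240.0, 280.0)
        a_slope = rng.uniform(-1.5, 0.0)
        migration = MigrationParams(
            spring_mean=arrival60 - 60.0 * s_slope,
            spring_lat_slope=s_slope,
            spring_sd=rng.uniform(3.0, 8.0),
            autumn_mean=a_depart60 - 60.0 * a_slope,
            autumn_lat_slope=a_slope,
            autumn_sd=rng.uniform(6.0, 12.0),
            is_migratory=is_migratory,
        )
        detection = DetectionCoefficients(
            intercept=rng.uniform(-2.8, -1.8),
            day_coefs=tuple(rng.uniform(-0.5, 0.5, 4)),
            time_coefs=tuple(rng.uniform(-0.8, 0.8, 4)),
        )
        translation = TranslationParams(
            alpha=rng.uniform(0.0, 0.6),
            beta_direct=rng.uniform(0.3, 0.8),
            beta_interval=rng.uniform(-0.1, 0.2),
            beta_point=rng.uniform(0.1, 0.4),
            gamma=rng.uniform(0.6, 1.0),
        )
        species.append(
            SpeciesTruth(
                species_id=f"sp{k:02d}",
                migration=migration,
                detection=detection,
                translation=translation,
                spatial_field=RasterLayer(grid=grid, values=vals),
            )
        )
    return SyntheticWorld(
        grid=grid,
        species=tuple(species),
        lat_north_deg=lat_north_deg,
        lat_south_deg=lat_south_deg,
        seed=seed,
    )


def perturb_prior(
    world: SyntheticWorld,
    spatial_shift_sd: float = 0.5,
    migration_shift_days: float = 5.0,
    prior_sd_const: float = 0.15,
    seed: int = 1,
    shift_sigma_cells: float = 50.0,
) -> dict[str, SpeciesPriorBundle]:
    """Prior maps and parameter tables that deviate controllably from truth.

    The prior spatial mean is Phi(Phi^{-1}(truth) + smooth probit-scale noise
    with sd ``spatial_shift_sd``); the prior sd layer is the constant
    ``prior_sd_const``; prior migration means are shifted by independent
    Normal(0, migration_shift_days^2) draws.  Zero shifts reproduce the truth.
    The translation parameters in the returned bundles are zero placeholders:
    they must be fitted from a burn-in stream before evaluation.
    """
    if spatial_shift_sd < 0 or migration_shift_days < 0:
        raise ValueError("shift magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    bundles: dict[str, SpeciesPriorBundle] = {}
    for sp in world.species:
        truth = sp.spatial_field.values
        if spatial_shift_sd > 0:
            shift = spatial_shift_sd * _smooth_field(rng, truth.shape, shift_sigma_cells)
        else:
            shift = np.zeros_like(truth)
        prior_vals = np.clip(ndtr(ndtri(np.clip(truth, 1e-9, 1 - 1e-9)) + shift), 1e-6, 1 - 1e-6)
        fine_mean = RasterLayer(grid=world.grid, values=prior_vals)
        fine_var = RasterLayer(grid=world.grid, values=np.full_like(prior_vals, prior_sd_const**2))
        coarse_mean, coarse_var = downsample_prior(fine_mean, fine_var)
        coarse_sd = RasterLayer(grid=coarse_mean.grid, values=np.sqrt(coarse_var.values))
        mig = sp.migration
        if mig.is_migratory and migration_shift_days > 0:
            mig = MigrationParams(
                spring_mean=mig.spring_mean + rng.normal(0, migration_shift_days),
                spring_lat_slope=mig.spring_lat_slope,
                spring_sd=mig.spring_sd,
                autumn_mean=mig.autumn_mean + rng.normal(0, migration_shift_days),
                autumn_lat_slope=mig.autumn_lat_slope,
                autumn_sd=mig.autumn_sd,
                is_migratory=True,
            )
        bundles[sp.species_id] = SpeciesPriorBundle(
            migration=mig,
            detection=sp.detection,
            translation=TranslationParams(),
            fine_mean=fine_mean,
            coarse_mean=coarse_mean,
            coarse_sd=coarse_sd,
        )
    return bundles


def simulate_pam(
    world: SyntheticWorld,
    station_cells: list[CellIndex],
    days,
    year: int = 2023,
    seed: int = 0,
    minute_step: int = 10,
) -> list[PamRecord]:
    """1-minute passive segments at fixed stations, one every ``minute_step`` minutes.

    Detections are Bernoulli(m * s_true * d_PAM_true) per species.
    """
    for cell in station_cells:
        if not world.grid.contains(cell):
            raise ValueError("stations must lie within the grid")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    days = np.asarray(list(days), dtype=int)
    minutes = np.arange(0, 1440, minute_step)
    records: list[PamRecord] = []
    # probability cube per species: (station, day, minute)
    for si, cell in enumerate(station_cells):
        lat = world.latitude_of_row(cell.row)
        dd, mm = np.meshgrid(days, minutes, indexing="ij")
        probs = []
        for sp in world.species:
            m = migration_probability(sp.migration, lat, dd)
            s = sp.spatial_field.values[cell.row, cell.col]
            d = predict_d_pam(sp.detection, day_fraction(dd), minute_fraction(mm))
            probs.append(m * s * d)
        pcube = np.stack(probs, axis=-1)  # (day, minute, species)
        draws = rng.random(pcube.shape) < pcube
        for di, day in enumerate(days):
            for mi, minute in enumerate(minutes):
                records.append(
                    PamRecord(
                        site_id=f"station{si}",
                        timestamp=Timestamp(year, int(day), int(minute)),
                        detections=tuple(int(v) for v in draws[di, mi]),
                    )
                )
    return records


def _vocal_activity_by_minute(world: SyntheticWorld, day: int) -> np.ndarray:
    """Expected per-minute vocal activity summed over species (trigger weight)."""
    minutes = np.arange(_ACTIVE_START, _ACTIVE_END)
    total = np.zeros(minutes.size)
    for sp in world.species:
        total += predict_d_pam(sp.detection, day_fraction(day), minute_fraction(minutes))
    return total


def simulate_mk_stream(
    world: SyntheticWorld,
    observers: ObserverPopulation,
    days,
    year: int = 2024,
    seed: int = 0,
) -> DetectionMatrix:
    """App-style recording stream with Bernoulli detections from the product model.

    Direct recordings are short (log-normal duration around half a minute) and
    their start times are biased toward minutes of high expected vocal
    activity in proportion to the trigger bias b (uniform when b = 0).
    Interval sessions emit 1-minute segments every 10 minutes; point counts
    are 5-minute recordings at fixed stations.  Detection probabilities use
    the species' true translation parameters.
    """
    timing_seed, detection_seed = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(timing_seed)
    days = [int(d) for d in days]
    n_users = len(observers.home_cells)
    user_type = rng.choice(3, size=n_users, p=list(observers.type_mix))

    recs: list[RecordingMeta] = []
    rid = 0
    for day in days:
        activity = _vocal_activity_by_minute(world, day)
        weights = 1.0 + observers.trigger_bias * activity
        weights = weights / weights.sum()
        minutes_axis = np.arange(_ACTIVE_START, _ACTIVE_END)
        for u in range(n_users):
            home = observers.home_cells[u]
            lat = world.latitude_of_row(home.row)
            if user_type[u] == 0:  # direct
                n_rec = rng.poisson(observers.direct_rate_per_day)
                if n_rec == 0:
                    continue
                start_minutes = rng.choice(minutes_axis, size=n_rec, p=weights)
                durations = np.clip(np.exp(rng.normal(np.log(0.55), 0.6, n_rec)), 0.1, 10.0)
                for minute, dur in zip(start_minutes, durations):
                    recs.append(
                        RecordingMeta(
                            recording_id=f"r{rid}",
                            timestamp=Timestamp(year, day, int(minute)),
                            cell=home,
                            latitude_deg=lat,
                            rec_type="direct",
                            duration_min=float(dur),
                        )
                    )
                    rid += 1
            elif user_type[u] == 1:  # interval session
                if rng.random() >= observers.interval_session_prob:
                    continue
                start = int(rng.integers(_ACTIVE_START, _ACTIVE_END - 60))
                n_seg = int(rng.integers(6, 37))  # 1-6 hours of 10-min cycles
                for k in range(n_seg):
                    minute = start + 10 * k
                    if minute >= 1440:
                        break
                    recs.append(
                        RecordingMeta(
                            recording_id=f"r{rid}",
                            timestamp=Timestamp(year, day, minute),
                            cell=home,
                            latitude_deg=lat,
                            rec_type="interval",
                            duration_min=1.0,
                        )
                    )
                    rid += 1
            else:  # point count
                if not observers.point_station_cells or rng.random() >= observers.point_visit_prob:
                    continue
                cell = observers.point_station_cells[int(rng.integers(len(observers.point_station_cells)))]
                minute = int(rng.integers(_ACTIVE_START, _ACTIVE_END))
                recs.append(
                    RecordingMeta(
                        recording_id=f"r{rid}",
                        timestamp=Timestamp(year, day, minute),
                        cell=cell,
                        latitude_deg=world.latitude_of_row(cell.row),
                        rec_type="point",
                        duration_min=5.0,
                    )
                )
                rid += 1

    # vectorized detection draws from the product model
    det_rng = np.random.default_rng(detection_seed)
    n = len(recs)
    day_arr = np.array([r.timestamp.day_of_year for r in recs])
    minute_arr = np.array([r.timestamp.minute_of_day for r in recs])
    lat_arr = np.array([r.latitude_deg for r in recs])
    row_arr = np.array([r.cell.row for r in recs])
    col_arr = np.array([r.cell.col for r in recs])
    logdur = np.array([r.log_duration for r in recs])
    type_codes = np.array([("direct", "interval", "point").index(r.rec_type) for r in recs])
    values = np.zeros((n, len(world.species)), dtype=np.int8)
    if n:
        dfrac, mfrac = day_fraction(day_arr), minute_fraction(minute_arr)
        for k, sp in enumerate(world.species):
            m = migration_probability(sp.migration, lat_arr, day_arr)
            s = sp.spatial_field.values[row_arr, col_arr]
            dpam = predict_d_pam(sp.detection, dfrac, mfrac)
            dmk = d_mk(sp.translation, type_codes, logdur, dpam)
            p = m * s * dmk
            values[:, k] = det_rng.random(n) < p
    return DetectionMatrix(recordings=recs, species_ids=world.species_ids, values=values)
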