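"""Predictive evaluation: factorized predictions, AUC and walk-forward forecasting.

A recording-level prediction is the product p = p_M * p_S * p_D of the
migration, spatial and detection components.  The walk-forward evaluation
mimics nightly operation: for each schedule day T, the migration and spatial
posteriors are refitted on all records up to T and the next forecast window
(T, T + window] is predicted; predictions are pooled across all test periods
before computing one AUC per species for the prior and the posterior model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .core import DetectionMatrix, GridSpec, RasterLayer, day_fraction, minute_fraction
from .posterior_detection import TranslationParams, d_mk
from .posterior_migration import MigrationUpdateConfig, fit_posterior_migration
from .posterior_spatial import SpatialUpdateConfig, update_raster, upsample_raster
from .prior_detection import DetectionCoefficients, predict_d_pam
from .prior_migration import MigrationParams, migration_probability

__all__ = [
    "PredictionSet",
    "WalkForwardConfig",
    "SpeciesPriorBundle",
    "predict_recording",
    "auc",
    "relative_auc_gain",
    "walk_forward",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionSet:
    recording_id: str
    species_id: str
    model_tag: str  # "prior" | "posterior"
    probability: float

    def __post_init__(self) -> None:
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must lie in [0, 1]")
        if self.model_tag not in ("prior", "posterior"):
            raise ValueError("model_tag must be 'prior' or 'posterior'")


@dataclass(frozen=True)
class WalkForwardConfig:
    """Schedule of refit days T and forecast windows (T, T + window]."""

    start_day: int
    end_day: int
    forecast_window_days: int = 1
    min_detections_per_species: int = 100

    def __post_init__(self) -> None:
        if self.forecast_window_days < 1:
            raise ValueError("forecast window must be at least one day")
        if self.end_day < self.start_day:
            raise ValueError("end_day must not precede start_day")

    @property
    def schedule(self) -> range:
        return range(self.start_day, self.end_day + 1, self.forecast_window_days)


@dataclass
class SpeciesPriorBundle:
    """Everything the twin knows about one species before seeing stream data."""

    migration: MigrationParams
    detection: DetectionCoefficients
    translation: TranslationParams
    fine_mean: RasterLayer
    coarse_mean: RasterLayer
    coarse_sd: RasterLayer


def predict_recording(m: float, s: float, d: float) -> float:
    """Detection probability of one recording: the product of the three components."""
    for v in (m, s, d):
        if not 0 <= v <= 1:
            raise ValueError("components must lie in [0, 1]")
    return m * s * d


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted half: U / (n1 * n0).

    Returns NaN when only one class is present (the value is undefined).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0 or labels.min() == labels.max():
        return float("nan")
    return float(roc_auc_score(labels, scores))


def relative_auc_gain(auc_prior: float, auc_posterior: float, baseline: float = 0.5) -> float:
    """Percent improvement of the AUC excess over the chance baseline.

    100 * (auc_posterior - auc_prior) / (auc_prior - baseline), rounded to the
    nearest integer percent; NaN when the prior does not beat the baseline.
    """
    if not auc_prior > baseline:
        return float("nan")
    return float(round(100.0 * (auc_posterior - auc_prior) / (auc_prior - baseline)))


def _species_static_arrays(meta: pd.DataFrame, bundle: SpeciesPriorBundle, fine_grid: GridSpec):
    """Per-recording covariates that do not change across walk-forward steps."""
    day = meta["day_of_year"].to_numpy()
    lat = meta["latitude_deg"].to_numpy()
    dpam = predict_d_pam(
        bundle.detection, day_fraction(day), minute_fraction(meta["minute_of_day"].to_numpy())
    )
    rec_codes = meta["rec_type"].cat.codes.to_numpy()
    dmk = d_mk(bundle.translation, rec_codes, meta["log_duration"].to_numpy(), dpam)
    m_prior = migration_probability(bundle.migration, lat, day)
    fr = meta["row"].to_numpy()
    fc = meta["col"].to_numpy()
    s_prior_fine = bundle.fine_mean.values[fr, fc]
    factor = round(bundle.coarse_mean.grid.cell_size_km / fine_grid.cell_size_km)
    crow, ccol = fr // factor, fc // factor
    return day, lat, dmk, m_prior, s_prior_fine, crow, ccol, fr, fc


def walk_forward(
    stream: DetectionMatrix,
    fine_grid: GridSpec,
    priors: dict[str, SpeciesPriorBundle],
    config: WalkForwardConfig,
    spatial_config: SpatialUpdateConfig | None = None,
    migration_config: MigrationUpdateConfig | None = None,
) -> pd.DataFrame:
    """Walk-forward next-window evaluation of prior vs posterior predictions.

    The detection translation inside each bundle must already be fitted on a
    burn-in period preceding ``config.start_day`` (it is not refitted here).
    Returns a table with one row per retained species: species_id,
    n_detections, auc_prior, auc_posterior, delta.
    """
    if spatial_config is None:
        spatial_config = SpatialUpdateConfig()
    if migration_config is None:
        migration_config = MigrationUpdateConfig()
    meta = stream.meta_frame()
    rows = []
    for sp in stream.species_ids:
        if sp not in priors:
            logger.info("species %s skipped: no prior bundle", sp)
            continue
        bundle = priors[sp]
        y_all = stream.species_column(sp).astype(float)
        n_det = int(y_all.sum())
        if n_det < config.min_detections_per_species:
            logger.info("species %s skipped: %d detections below threshold", sp, n_det)
            continue
        day, lat, dmk, m_prior, s_prior_fine, crow, ccol, fr, fc = _species_static_arrays(
            meta, bundle, fine_grid
        )
        labels, prior_scores, post_scores = [], [], []
        for T in config.schedule:
            train = day <= T
            test = (day > T) & (day <= T + config.forecast_window_days)
            if not test.any():
                logger.info("species %s: empty test period after T=%d", sp, T)
                continue
            assert day[train].max(initial=-1) <= T, "walk-forward leakage"
            # migration posterior (spatial fixed at the prior)
            theta_post = fit_posterior_migration(
                y_all[train],
                lat[train],
                day[train],
                np.clip(s_prior_fine[train] * dmk[train], 1e-12, 1 - 1e-12),
                bundle.migration,
                migration_config,
            )
            m_post_train = migration_probability(theta_post, lat[train], day[train])
            # spatial posterior from season-to-date records
            post_coarse, _ = update_raster(
                y_all[train],
                np.clip(m_post_train * dmk[train], 1e-12, 1 - 1e-12),
                crow[train],
                ccol[train],
                bundle.coarse_mean,
                bundle.coarse_sd,
                spatial_config,
            )
            post_fine = upsample_raster(post_coarse, bundle.fine_mean)
            m_post_test = migration_probability(theta_post, lat[test], day[test])
            s_post_test = post_fine.values[fr[test], fc[test]]
            labels.append(y_all[test])
            prior_scores.append(m_prior[test] * s_prior_fine[test] * dmk[test])
            post_scores.append(m_post_test * s_post_test * dmk[test])
        if not labels:
            continue
        labels_v = np.concatenate(labels)
        auc_prior = auc(np.concatenate(prior_scores), labels_v)
        auc_post = auc(np.concatenate(post_scores), labels_v)
        rows.append(
            {
                "species_id": sp,
                "n_detections": n_det,
                "auc_prior": auc_prior,
                "auc_posterior": auc_post,
                "delta": auc_post - auc_prior,
            }
        )
    return pd.DataFrame(rows, columns=["species_id", "n_detections", "auc_prior", "auc_posterior", "delta"])
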