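"""Prior vocal-detection model from passive acoustic monitoring (PAM) data.

The prior detection component d^PAM_j(t) is the probability that species j,
conditional on being present, is detected in a single 1-minute passive
recording at calendar time t.  It is a logistic regression of the per-minute
binary detection on periodic (first and second harmonic) functions of the day
of year and the time of day, fitted only to data inside the species'
presence window at each site-year (between the 5% and 95% accumulation
quantiles of that year's detections), so the seasonal curve reflects vocal
activity conditional on presence rather than migration timing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import Timestamp, day_fraction, minute_fraction

__all__ = [
    "DetectionCoefficients",
    "PamRecord",
    "FitError",
    "periodic_features",
    "presence_window",
    "fit_prior_detection",
    "predict_d_pam",
    "read_detection_table",
    "write_detection_table",
]


class FitError(RuntimeError):
    """A model fit failed (degenerate response, separation or non-convergence)."""


COEF_NAMES = [
    "intercept",
    "d_sin1",
    "d_cos1",
    "d_sin2",
    "d_cos2",
    "t_sin1",
    "t_cos1",
    "t_sin2",
    "t_cos2",
]


@dataclass(frozen=True)
class DetectionCoefficients:
    """Nine coefficients of the periodic logistic detection model.

    Order: intercept; sin/cos of the first and second day-of-year harmonics;
    sin/cos of the first and second time-of-day harmonics.
    """

    intercept: float
    day_coefs: tuple[float, float, float, float]
    time_coefs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        vec = self.as_array()
        if vec.shape != (9,) or not np.isfinite(vec).all():
            raise ValueError("DetectionCoefficients requires 9 finite values")

    def as_array(self) -> np.ndarray:
        return np.array([self.intercept, *self.day_coefs, *self.time_coefs], dtype=float)

    @classmethod
    def from_array(cls, vec) -> "DetectionCoefficients":
        vec = np.asarray(vec, dtype=float)
        return cls(float(vec[0]), tuple(vec[1:5]), tuple(vec[5:9]))


@dataclass(frozen=True)
class PamRecord:
    """One 1-minute passive recording segment with its binary detection vector."""

    site_id: str
    timestamp: Timestamp
    detections: tuple[int, ...]


def periodic_features(day_frac, time_frac) -> np.ndarray:
    """First- and second-harmonic sin/cos basis of both unit fractions.

    Returns (sin 2*pi*d, cos 2*pi*d, sin 4*pi*d, cos 4*pi*d, then the same four
    of the time fraction); vectorized, output shape (..., 8).
    """
    d = np.asarray(day_frac, dtype=float)
    t = np.asarray(time_frac, dtype=float)
    if ((d < 0) | (d >= 1)).any() or ((t < 0) | (t >= 1)).any():
        raise ValueError("fractions must lie in [0, 1)")
    d, t = np.broadcast_arrays(d, t)
    two_pi_d, two_pi_t = 2 * np.pi * d, 2 * np.pi * t
    feats = np.stack(
        [
            np.sin(two_pi_d),
            np.cos(two_pi_d),
            np.sin(2 * two_pi_d),
            np.cos(2 * two_pi_d),
            np.sin(two_pi_t),
            np.cos(two_pi_t),
            np.sin(2 * two_pi_t),
            np.cos(2 * two_pi_t),
        ],
        axis=-1,
    )
    return feats


def presence_window(detection_days: Sequence[int]) -> tuple[int, int]:
    """Days bracketing the central 90% of detections for one site-year-species.

    The window starts at the day of the ceil(0.05 n)-th detection in
    chronological order and ends at the day of the ceil(0.95 n)-th.
    """
    days = np.sort(np.asarray(detection_days, dtype=int))
    n = days.size
    if n == 0:
        raise ValueError("presence_window requires at least one detection")
    lo = int(np.ceil(0.05 * n)) - 1
    hi = int(np.ceil(0.95 * n)) - 1
    return int(days[lo]), int(days[hi])


def _design(records: Sequence[PamRecord]) -> np.ndarray:
    days = np.array([r.timestamp.day_of_year for r in records])
    mins = np.array([r.timestamp.minute_of_day for r in records])
    feats = periodic_features(day_fraction(days), minute_fraction(mins))
    return np.column_stack([np.ones(len(records)), feats])


def fit_prior_detection(records: Sequence[PamRecord], species_index: int) -> DetectionCoefficients:
    """Maximum-likelihood periodic logistic fit for one species.

    ``records`` should already be restricted to the species' presence windows.
    Raises :class:`FitError` on a single-class response or non-convergence
    (e.g. complete separation); there is no silent fallback because data-poor
    species require externally supplied coefficients.
    """
    y = np.array([r.detections[species_index] for r in records], dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise FitError("response must contain both detections and non-detections")
    X = _design(records)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        res = model.fit(tol=1e-10, maxiter=200)
    except Exception as exc:  # perfect separation raises inside IRLS
        raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.converged or not np.isfinite(res.params).all() or np.abs(res.params).max() > 50:
        raise FitError("logistic fit did not converge (possible separation)")
    return DetectionCoefficients.from_array(res.params)


def predict_d_pam(coefs: DetectionCoefficients, day_frac, time_frac):
    """Detection probability per 1-minute passive segment; periodic in both args."""
    feats = periodic_features(day_frac, time_frac)
    eta = coefs.intercept + feats @ np.asarray(coefs.day_coefs + coefs.time_coefs)
    out = 1.0 / (1.0 + np.exp(-eta))
    return float(out) if np.ndim(out) == 0 else out


# --- coefficient table I/O -------------------------------------------------


def write_detection_table(coefs: dict[str, DetectionCoefficients], path: str | Path) -> None:
    rows = [{"species_id": sp, **dict(zip(COEF_NAMES, c.as_array()))} for sp, c in coefs.items()]
    pd.DataFrame(rows, columns=["species_id"] + COEF_NAMES).to_csv(path, index=False)


def read_detection_table(path: str | Path) -> dict[str, DetectionCoefficients]:
    frame = pd.read_csv(path)
    return {
        str(r["species_id"]): DetectionCoefficients.from_array([r[c] for c in COEF_NAMES])
        for _, r in frame.iterrows()
    }
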