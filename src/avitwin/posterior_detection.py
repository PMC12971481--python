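"""Probit translation of the passive-monitoring detection model to app recordings.

App recordings differ from the 1-minute passive segments the prior detection
model was fitted to: they are mostly short opportunistic clips of three types
(direct, interval, point) with varying duration.  The translated detection
probability is

    d^MK = Phi( alpha + beta_{rec_type} * log_duration + gamma * Phi^{-1}(d^PAM) )

with independent Normal(0, 5^2) priors on the five coefficients.  The MAP
estimate is obtained by minimizing the penalized Bernoulli deviance with the
migration and spatial components fixed at their prior values, and is then used
as a plug-in; it is refreshed once per year on all accumulated data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .prior_detection import FitError

__all__ = [
    "TranslationParams",
    "PRIOR_SD",
    "d_mk",
    "translation_neg_log_posterior",
    "translation_grad",
    "fit_translation",
    "read_translation_table",
    "write_translation_table",
]

logger = logging.getLogger(__name__)

PRIOR_SD = 5.0  # Normal(0, 5^2) prior on every coefficient
_EPS = 1e-9
_REC_TYPE_INDEX = {"direct": 0, "interval": 1, "point": 2}


@dataclass(frozen=True)
class TranslationParams:
    alpha: float = 0.0
    beta_direct: float = 0.0
    beta_interval: float = 0.0
    beta_point: float = 0.0
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.as_array()).all():
            raise ValueError("translation parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.alpha, self.beta_direct, self.beta_interval, self.beta_point, self.gamma],
            dtype=float,
        )

    @classmethod
    def from_array(cls, vec) -> "TranslationParams":
        a, bd, bi, bp, g = (float(v) for v in vec)
        return cls(a, bd, bi, bp, g)


def _rec_type_codes(rec_types) -> np.ndarray:
    if isinstance(rec_types, str):
        return np.array([_REC_TYPE_INDEX[rec_types]])
    arr = np.asarray(rec_types)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    return np.array([_REC_TYPE_INDEX[str(r)] for r in arr.ravel()]).reshape(arr.shape)


def _clamped_probit(d_pam) -> np.ndarray:
    d = np.asarray(d_pam, dtype=float)
    if ((d <= 0) | (d >= 1)).any():
        logger.warning("d_pam at 0 or 1 clamped to [1e-9, 1-1e-9] before probit")
        d = np.clip(d, _EPS, 1 - _EPS)
    return ndtri(d)


def _linear_predictor(params: TranslationParams, rec_types, log_duration, d_pam):
    codes = _rec_type_codes(rec_types)
    betas = np.array([params.beta_direct, params.beta_interval, params.beta_point])
    x = np.asarray(log_duration, dtype=float)
    return params.alpha + betas[codes].reshape(x.shape) * x + params.gamma * _clamped_probit(d_pam)


def d_mk(params: TranslationParams, rec_type, log_duration, d_pam):
    """App-recording detection probability Phi(alpha + beta_r x + gamma Phi^{-1}(d_pam))."""
    scalar = np.ndim(log_duration) == 0 and isinstance(rec_type, str)
    eta = _linear_predictor(
        params,
        rec_type if not scalar else [rec_type],
        np.atleast_1d(log_duration),
        np.atleast_1d(d_pam),
    )
    out = ndtr(eta)
    return float(out[0]) if scalar else out


def _nll_terms(p, y):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -(y * np.log(p) + (1 - y) * np.log1p(-p))


def translation_neg_log_posterior(vec, y, rec_codes, log_dur, probit_dpam, ms) -> float:
    """Penalized Bernoulli deviance for the five translation parameters.

    ``vec`` is (alpha, beta_direct, beta_interval, beta_point, gamma);
    ``ms`` is the fixed per-recording product of the prior migration and
    spatial probabilities.  The penalty is sum(vec^2) / (2 * 5^2).
    """
    alpha, betas, gamma = vec[0], np.asarray(vec[1:4]), vec[4]
    eta = alpha + betas[rec_codes] * log_dur + gamma * probit_dpam
    p = ms * ndtr(eta)
    bad = ((p <= 0) & (y == 1)) | ((p >= 1) & (y == 0))
    if bad.any():
        logger.warning("degenerate success probabilities clamped in translation objective")
    return float(_nll_terms(p, y).sum() + (np.asarray(vec) ** 2).sum() / (2 * PRIOR_SD**2))


def translation_grad(vec, y, rec_codes, log_dur, probit_dpam, ms) -> np.ndarray:
    """Analytic gradient of :func:`translation_neg_log_posterior`."""
    alpha, betas, gamma = vec[0], np.asarray(vec[1:4]), vec[4]
    eta = alpha + betas[rec_codes] * log_dur + gamma * probit_dpam
    d = ndtr(eta)
    p = np.clip(ms * d, 1e-12, 1 - 1e-12)
    # dNLL/dp * dp/deta;  dp/deta = ms * phi(eta)
    dnll_dp = -(y / p) + (1 - y) / (1 - p)
    deta = dnll_dp * ms * norm.pdf(eta)
    g = np.empty(5)
    g[0] = deta.sum()
    for k in range(3):
        mask = rec_codes == k
        g[1 + k] = (deta[mask] * log_dur[mask]).sum()
    g[4] = (deta * probit_dpam).sum()
    return g + np.asarray(vec) / PRIOR_SD**2


def fit_translation(
    y,
    rec_types,
    log_duration,
    d_pam,
    ms,
    *,
    tol: float = 1e-6,
    maxiter: int = 10_000,
) -> TranslationParams:
    """MAP fit of the translation parameters for one species.

    Inputs are per-recording arrays: binary detections ``y``, recording types,
    log-durations, prior detection probabilities ``d_pam`` and the fixed
    migration x spatial product ``ms``.  Deterministic: initialized at zero,
    quasi-Newton descent, stopping when the gradient sup-norm drops below
    ``tol``.  Raises :class:`FitError` if the response is single-class or the
    iteration cap is reached.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0 or y.min() == y.max():
        raise FitError("translation fit needs both detections and non-detections")
    rec_codes = _rec_type_codes(rec_types)
    log_dur = np.asarray(log_duration, dtype=float)
    probit_dpam = _clamped_probit(d_pam)
    ms = np.asarray(ms, dtype=float)
    # sort by recording id-independent keys so the reduction order (and hence
    # the float result) does not depend on input ordering
    order = np.lexsort((probit_dpam, log_dur, rec_codes, y))
    args = (y[order], rec_codes[order], log_dur[order], probit_dpam[order], ms[order])
    res = minimize(
        translation_neg_log_posterior,
        np.zeros(5),
        args=args,
        jac=translation_grad,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": tol, "ftol": 1e-14},
    )
    x = res.x
    # Newton polish with a finite-difference Hessian of the analytic gradient:
    # quasi-Newton alone can stall with the gradient sup-norm above tolerance
    h = 1e-6
    for _ in range(50):
        g = translation_grad(x, *args)
        if np.abs(g).max() < tol:
            break
        H = np.empty((5, 5))
        for k in range(5):
            e = np.zeros(5)
            e[k] = h
            H[:, k] = (translation_grad(x + e, *args) - translation_grad(x - e, *args)) / (2 * h)
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        x_new = x - step
        if translation_neg_log_posterior(x_new, *args) >= translation_neg_log_posterior(x, *args) + 1e-12:
            break
        x = x_new
    grad_norm = float(np.abs(translation_grad(x, *args)).max())
    if grad_norm > 1e-3:
        raise FitError(
            f"translation fit did not converge: grad sup-norm {grad_norm:.2e}, last iterate {x}"
        )
    return TranslationParams.from_array(x)


# --- parameter table I/O ---------------------------------------------------

_COLS = ["species_id", "alpha", "beta_direct", "beta_interval", "beta_point", "gamma", "fit_year"]


def write_translation_table(
    params: Mapping[str, TranslationParams], fit_year: Mapping[str, int], path: str | Path
) -> None:
    rows = [
        {
            "species_id": sp,
            "alpha": p.alpha,
            "beta_direct": p.beta_direct,
            "beta_interval": p.beta_interval,
            "beta_point": p.beta_point,
            "gamma": p.gamma,
            "fit_year": fit_year.get(sp, 0),
        }
        for sp, p in params.items()
    ]
    pd.DataFrame(rows, columns=_COLS).to_csv(path, index=False)


def read_translation_table(path: str | Path) -> tuple[dict[str, TranslationParams], dict[str, int]]:
    frame = pd.read_csv(path)
    params, years = {}, {}
    for _, r in frame.iterrows():
        sp = str(r["species_id"])
        params[sp] = TranslationParams(
            float(r["alpha"]),
            float(r["beta_direct"]),
            float(r["beta_interval"]),
            float(r["beta_point"]),
            float(r["gamma"]),
        )
        years[sp] = int(r["fit_year"])
    return params, years
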