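"""Local-likelihood update of the spatial occurrence surface.

Each (coarse, 1 km^2) cell's occurrence probability s is updated independently
by maximizing a *local* log-likelihood: Bernoulli terms of all records, with
each record weighted by a Gaussian kernel K(c, c0) = exp(-tau dist(c, c0)^2/2)
of the distance between its cell and the focal cell, plus the log-density of a
Normal(prior_mean, prior_sd) prior truncated to [0, 1].  The per-record
success probability is p_i(s) = m_i * s * d_i with the migration and detection
components fixed.  Posterior spread comes from a Laplace approximation
(inverse square root of the negative curvature at the mode).

With tau = 1/2.5^2 (the default) cells within roughly 7.5 km (three kernel
standard deviations, where the implementation truncates the kernel to exactly
zero) influence the focal cell; tau = 0 recovers one pooled likelihood shared
by all cells, and very large tau uses focal-cell data only.

The update runs on the coarse grid: fine (1 ha) prior means/variances are
block-averaged down, and the coarse posterior is mapped back to the fine grid
by a probit-scale shift of the fine priors that preserves their within-block
geometry while matching the block mean to the coarse posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import brentq, minimize_scalar

from .core import CellIndex, GridSpec, RasterLayer, std_normal_cdf, std_normal_quantile

__all__ = [
    "SpatialUpdateConfig",
    "kernel_weight",
    "local_log_likelihood",
    "update_cell",
    "update_raster",
    "downsample_prior",
    "probit_prior_moments",
    "upsample_posterior",
    "upsample_raster",
]

logger = logging.getLogger(__name__)

_S_LO, _S_HI = 1e-6, 1 - 1e-6


@dataclass(frozen=True)
class SpatialUpdateConfig:
    """Kernel precision (per km^2), truncation radius (km) and coarse cell size."""

    tau_spatial: float = 1.0 / 2.5**2
    truncation_radius_km: float = 7.5
    coarse_cell_km: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_spatial < 0:
            raise ValueError("tau_spatial must be non-negative")


def kernel_weight(distance_km, tau, truncation_radius_km: float = 7.5):
    """Gaussian kernel exp(-tau d^2 / 2), hard-truncated to zero beyond the radius.

    With tau = 0 the kernel is identically 1 (no truncation): every cell gets
    equal weight and the local likelihood reduces to the pooled one.
    """
    d = np.asarray(distance_km, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if tau == 0:
        out = np.ones_like(d)
    else:
        out = np.exp(-tau * d**2 / 2.0)
        out = np.where(d > truncation_radius_km, 0.0, out)
    return float(out) if out.ndim == 0 else out


def _weights_for_focal(
    focal: CellIndex, rows, cols, grid: GridSpec, tau: float, truncation_radius_km: float
) -> np.ndarray:
    d = np.hypot(np.asarray(rows) - focal.row, np.asarray(cols) - focal.col) * grid.cell_size_km
    return kernel_weight(d, tau, truncation_radius_km)


def local_log_likelihood(
    s: float,
    focal: CellIndex,
    y,
    md,
    rows,
    cols,
    grid: GridSpec,
    tau: float,
    truncation_radius_km: float = 7.5,
) -> float:
    """Kernel-weighted Bernoulli log-likelihood at occurrence probability ``s``.

    ``y`` are binary detections, ``md`` the fixed per-record migration x
    detection products and (rows, cols) the records' cells on ``grid``.
    """
    if not 0 < s < 1:
        raise ValueError("s must lie strictly inside (0, 1)")
    w = _weights_for_focal(focal, rows, cols, grid, tau, truncation_radius_km)
    p = np.asarray(md, dtype=float) * s
    if ((p <= 0) | (p >= 1)).any():
        logger.warning("success probabilities clamped to [1e-12, 1-1e-12] in local likelihood")
        p = np.clip(p, 1e-12, 1 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float((w * (y * np.log(p) + (1 - y) * np.log1p(-p))).sum())


def update_cell(
    focal: CellIndex,
    y,
    md,
    rows,
    cols,
    grid: GridSpec,
    prior_mean: float,
    prior_sd: float,
    config: SpatialUpdateConfig | None = None,
) -> tuple[float, float]:
    """MAP and Laplace sd of the occurrence probability in one coarse cell.

    Maximizes local_log_likelihood(s) + log-density of the truncated
    Normal(prior_mean, prior_sd) prior over s in [1e-6, 1-1e-6] with bounded
    scalar minimization (tolerance 1e-9).  The Laplace sd is
    (-d^2/ds^2 log posterior)^{-1/2} at the mode, falling back to the prior sd
    when the curvature is non-negative.
    """
    if not 0 <= prior_mean <= 1 or prior_sd <= 0:
        raise ValueError("prior_mean must be in [0,1] and prior_sd positive")
    if config is None:
        config = SpatialUpdateConfig()
    w = _weights_for_focal(focal, rows, cols, grid, config.tau_spatial, config.truncation_radius_km)
    keep = w > 0
    w, yv, a = w[keep], np.asarray(y, dtype=float)[keep], np.asarray(md, dtype=float)[keep]

    def neg_log_post(s: float) -> float:
        p = np.clip(a * s, 1e-12, 1 - 1e-12)
        ll = (w * (yv * np.log(p) + (1 - yv) * np.log1p(-p))).sum()
        return -(ll - (s - prior_mean) ** 2 / (2 * prior_sd**2))

    res = minimize_scalar(neg_log_post, bounds=(_S_LO, _S_HI), method="bounded", options={"xatol": 1e-9})
    s_hat = float(res.x)
    # analytic curvature of the log posterior (concave in s)
    p = np.clip(a * s_hat, 1e-12, 1 - 1e-12)
    curv = float(-(w * (yv / s_hat**2 + (1 - yv) * a**2 / (1 - p) ** 2)).sum() - 1 / prior_sd**2)
    post_sd = (-curv) ** -0.5 if curv < 0 else prior_sd
    return s_hat, float(post_sd)


def update_raster(
    y,
    md,
    rows,
    cols,
    prior_mean: RasterLayer,
    prior_sd: RasterLayer,
    config: SpatialUpdateConfig | None = None,
    *,
    newton_iters: int = 200,
    tol: float = 1e-11,
    a_split: float = 0.9,
) -> tuple[RasterLayer, RasterLayer]:
    """Vectorized MAP update of every coarse cell at once.

    Same objective as :func:`update_cell` cell by cell, solved with a
    safeguarded Newton iteration exploiting the strict concavity of the log
    posterior in s.  The non-detection gradient terms a/(1 - a s) are expanded
    as geometric series in s, so the records collapse into per-cell power sums
    A_k[c] = sum_i a_i^k once per call and each Newton iteration touches only
    (n_terms x n_cells) numbers; records with a > ``a_split`` (where the
    series converges too slowly) keep an exact dense path.  Truncation error
    of the series is below 1e-12.  Returns (posterior mean layer, Laplace sd
    layer); nodata cells stay nodata.
    """
    if config is None:
        config = SpatialUpdateConfig()
    grid = prior_mean.grid
    n_rows, n_cols = grid.shape
    n_cells = n_rows * n_cols
    mu = prior_mean.values.ravel()
    sig = prior_sd.values.ravel()
    valid = ~np.isnan(mu) & ~np.isnan(sig)

    yv = np.asarray(y, dtype=float)
    a = np.clip(np.asarray(md, dtype=float), 1e-15, 1 - 1e-9)
    codes = np.asarray(rows, dtype=int) * n_cols + np.asarray(cols, dtype=int)

    # (n_cells, n_cells) kernel weights between coarse-cell centers, truncated
    cell_r, cell_c = np.divmod(np.arange(n_cells), n_cols)
    d = np.hypot(cell_r[:, None] - cell_r[None, :], cell_c[:, None] - cell_c[None, :]) * grid.cell_size_km
    W = kernel_weight(d, config.tau_spatial, config.truncation_radius_km)

    # detections: only the per-cell weighted count matters
    n1 = np.bincount(codes[yv == 1], minlength=n_cells).astype(float)
    n1w = W @ n1

    # non-detections, small a: per-cell power sums a^1..a^K
    small = (yv == 0) & (a <= a_split)
    big = (yv == 0) & (a > a_split)
    max_as = a_split * _S_HI
    K = max(8, int(np.ceil(np.log(1e-12) / np.log(max_as))))
    a_s, codes_s = a[small], codes[small]
    M = np.zeros((K, n_cells))
    if a_s.size:
        A = np.zeros((K, n_cells))
        powers = a_s.copy()
        for k in range(K):
            A[k] = np.bincount(codes_s, weights=powers, minlength=n_cells)
            powers *= a_s
        M = A @ W.T  # M[k, f] = sum_c W[f, c] A_{k+1}[c]
    Mh = M * np.arange(K)[:, None]  # derivative series coefficients (k-1) M_k
    W_big = W[:, codes[big]] if big.any() else None
    a_big = a[big]

    sig2 = np.where(valid, sig, 1.0) ** 2
    mu_f = np.where(valid, mu, 0.5)
    s = np.clip(mu_f, _S_LO, _S_HI)
    lo = np.full(n_cells, _S_LO)
    hi = np.full(n_cells, _S_HI)

    def series_eval(coefs: np.ndarray, s: np.ndarray) -> np.ndarray:
        """Horner evaluation of sum_k coefs[k] * s^k along axis 0."""
        out = coefs[-1].copy()
        for k in range(K - 2, -1, -1):
            out *= s
            out += coefs[k]
        return out

    def grad_hess(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        g = n1w / s - series_eval(M, s) - (s - mu_f) / sig2
        h = -n1w / s**2 - series_eval(Mh, s) / s - 1 / sig2
        if W_big is not None:
            r = 1.0 / (1.0 - a_big[None, :] * s[:, None])
            g -= (W_big * (a_big[None, :] * r)).sum(axis=1)
            h -= (W_big * (a_big[None, :] * r) ** 2).sum(axis=1)
        return g, h

    for _ in range(newton_iters):
        grad, curv = grad_hess(s)
        # maintain a bisection bracket around the root of the decreasing gradient
        lo = np.where(grad > 0, np.maximum(lo, s), lo)
        hi = np.where(grad < 0, np.minimum(hi, s), hi)
        s_new = s - grad / curv
        bad = (s_new <= lo) | (s_new >= hi) | ~np.isfinite(s_new)
        s_new = np.where(bad, 0.5 * (lo + hi), s_new)
        if np.abs(s_new - s).max() < tol:
            s = s_new
            break
        s = s_new
    s = np.clip(s, _S_LO, _S_HI)
    _, curv = grad_hess(s)
    post_sd = np.where(curv < 0, np.abs(curv) ** -0.5, np.sqrt(sig2))
    s = np.where(valid, s, np.nan)
    post_sd = np.where(valid, post_sd, np.nan)
    return (
        RasterLayer(grid=grid, values=s.reshape(n_rows, n_cols)),
        RasterLayer(grid=grid, values=post_sd.reshape(n_rows, n_cols)),
    )


def downsample_prior(
    fine_mean: RasterLayer, fine_var: RasterLayer, factor: int = 10
) -> tuple[RasterLayer, RasterLayer]:
    """Block-average fine means and variances onto the nesting coarse grid.

    Nodata fine cells are excluded from the averages; a fully-nodata block
    yields a nodata coarse cell.
    """
    coarse_grid = fine_mean.grid.coarsen(factor)
    out = []
    for layer in (fine_mean, fine_var):
        v = layer.values
        blocks = v.reshape(coarse_grid.n_rows, factor, coarse_grid.n_cols, factor).transpose(0, 2, 1, 3)
        flat = blocks.reshape(coarse_grid.n_rows, coarse_grid.n_cols, -1)
        n_valid = (~np.isnan(flat)).sum(axis=-1)
        total = np.nansum(flat, axis=-1)
        mean = np.where(n_valid > 0, total / np.maximum(n_valid, 1), np.nan)
        out.append(RasterLayer(grid=coarse_grid, values=mean))
    return out[0], out[1]


def probit_prior_moments(probit_mean: float, probit_var: float, n_nodes: int = 64) -> tuple[float, float]:
    """Mean and sd of Phi(Z), Z ~ Normal(probit_mean, probit_var).

    Probit-scale prior maps give the mean and variance of the linear
    predictor; the truncated-normal prior for the spatial update needs
    probability-scale moments.  Computed by Gauss-Hermite quadrature.
    """
    if probit_var < 0:
        raise ValueError("probit_var must be non-negative")
    if probit_var == 0:
        return float(std_normal_cdf(probit_mean)), 0.0
    nodes, weights = hermgauss(n_nodes)
    z = probit_mean + np.sqrt(2.0 * probit_var) * nodes
    vals = std_normal_cdf(z)
    mean = float((weights * vals).sum() / np.sqrt(np.pi))
    second = float((weights * vals**2).sum() / np.sqrt(np.pi))
    var = max(second - mean**2, 0.0)
    return mean, float(np.sqrt(var))


def upsample_posterior(coarse_posterior: float, fine_prior_block, *, literal: bool = False) -> np.ndarray:
    """Map one coarse posterior probability back onto its fine prior block.

    Default: fine posteriors are Phi(Phi^{-1}(prior_i) + delta) with delta the
    unique root of mean_i Phi(Phi^{-1}(prior_i) + delta) = coarse_posterior.
    This preserves the ranks (local geometry) of the fine priors and makes the
    block mean match the coarse posterior.

    ``literal=True`` instead minimizes the block squared error of a shifted
    *coarse* posterior, sum_i [Phi(Phi^{-1}(coarse) + delta) - prior_i]^2,
    which yields one constant value per block; it is exposed for comparison
    only.
    """
    prior = np.asarray(fine_prior_block, dtype=float)
    if ((prior <= 0) | (prior >= 1)).any():
        raise ValueError("fine priors must lie strictly inside (0, 1)")
    if not 0 < coarse_posterior < 1:
        logger.warning("coarse posterior at 0/1 clamped before upsampling")
        coarse_posterior = float(np.clip(coarse_posterior, 1e-9, 1 - 1e-9))
    if literal:
        probit_coarse = std_normal_quantile(coarse_posterior)

        def g(delta: float) -> float:
            return float(((std_normal_cdf(probit_coarse + delta) - prior) ** 2).sum())

        res = minimize_scalar(g, bounds=(-12.0, 12.0), method="bounded", options={"xatol": 1e-10})
        return np.full(prior.shape, std_normal_cdf(probit_coarse + float(res.x)))
    probit_prior = std_normal_quantile(prior)

    def h(delta: float) -> float:
        return float(std_normal_cdf(probit_prior + delta).mean() - coarse_posterior)

    delta_hat = brentq(h, -14.0, 14.0, xtol=1e-12)
    return std_normal_cdf(probit_prior + delta_hat)


def upsample_raster(
    coarse_posterior: RasterLayer, fine_prior: RasterLayer, factor: int = 10
) -> RasterLayer:
    """Apply :func:`upsample_posterior` block by block over a whole raster."""
    fg = fine_prior.grid
    out = np.full(fg.shape, np.nan)
    cp = coarse_posterior.values
    for r in range(coarse_posterior.grid.n_rows):
        for c in range(coarse_posterior.grid.n_cols):
            if np.isnan(cp[r, c]):
                continue
            block = fine_prior.values[r * factor : (r + 1) * factor, c * factor : (c + 1) * factor]
            vals = upsample_posterior(
                float(cp[r, c]), np.clip(block.ravel(), 1e-9, 1 - 1e-9)
            )
            out[r * factor : (r + 1) * factor, c * factor : (c + 1) * factor] = vals.reshape(
                factor, factor
            )
    return RasterLayer(grid=fg, values=out)
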