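import numpy as np
import pytest
from scipy.special import ndtr, ndtri

from avitwin.core import CellIndex, GridSpec, RasterLayer
from avitwin.posterior_spatial import (
    SpatialUpdateConfig,
    downsample_prior,
    kernel_weight,
    local_log_likelihood,
    probit_prior_moments,
    update_cell,
    update_raster,
    upsample_posterior,
    upsample_raster,
)

TAU = 1.0 / 2.5**2


class TestKernel:
    def test_unit_at_zero_distance(self):
        assert kernel_weight(0.0, TAU) == 1.0

    def test_one_kernel_sd(self):
        assert kernel_weight(2.5, TAU) == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert kernel_weight(2.5, TAU) == pytest.approx(0.60653, abs=1e-5)

    def test_truncation_boundary(self):
        assert kernel_weight(7.5, TAU) == pytest.approx(np.exp(-4.5), abs=1e-12)
        assert kernel_weight(7.5, TAU) == pytest.approx(0.011109, abs=1e-6)
        assert kernel_weight(7.51, TAU) == 0.0

    def test_tau_zero_is_flat(self):
        assert kernel_weight(50.0, 0.0) == 1.0


class TestLocalLogLikelihood:
    def test_tau_zero_reduces_to_pooled_likelihood(self, coarse_grid, rng):
        n = 300
        rows, cols = rng.integers(0, 8, n), rng.integers(0, 8, n)
        a = rng.uniform(0.05, 0.5, n)
        y = (rng.random(n) < 0.2).astype(float)
        s = 0.4
        pooled = (y * np.log(a * s) + (1 - y) * np.log1p(-a * s)).sum()
        val = local_log_likelihood(s, CellIndex(4, 4), y, a, rows, cols, coarse_grid, tau=0.0)
        assert val == pytest.approx(pooled, abs=1e-10)

    def test_focal_only_data(self, coarse_grid):
        y = np.array([1.0, 0.0, 0.0])
        a = np.array([0.3, 0.2, 0.4])
        rows = np.array([2, 2, 2]); cols = np.array([5, 5, 5])
        s = 0.6
        expected = (y * np.log(a * s) + (1 - y) * np.log1p(-a * s)).sum()
        val = local_log_likelihood(s, CellIndex(2, 5), y, a, rows, cols, coarse_grid, tau=TAU)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_double_loop(self, coarse_grid, rng):
        n = 120
        rows, cols = rng.integers(0, 8, n), rng.integers(0, 8, n)
        a = rng.uniform(0.05, 0.5, n)
        y = (rng.random(n) < 0.25).astype(float)
        s, focal = 0.35, CellIndex(3, 6)
        brute = 0.0
        for r in range(8):
            for c in range(8):
                d = np.hypot(r - focal.row, c - focal.col) * 1.0
                w = np.exp(-TAU * d**2 / 2) if d <= 7.5 else 0.0
                for i in range(n):
                    if rows[i] == r and cols[i] == c:
                        p = a[i] * s
                        brute += w * (y[i] * np.log(p) + (1 - y[i]) * np.log1p(-p))
        val = local_log_likelihood(s, focal, y, a, rows, cols, coarse_grid, tau=TAU)
        assert val == pytest.approx(brute, abs=1e-10)


class TestUpdateCell:
    def test_no_data_returns_prior_mode(self, coarse_grid):
        empty = np.zeros(0)
        s_hat, sd = update_cell(
            CellIndex(0, 0), empty, empty, empty.astype(int), empty.astype(int),
            coarse_grid, 0.37, 0.15,
        )
        assert s_hat == pytest.approx(0.37, abs=1e-6)
        assert sd == pytest.approx(0.15, abs=1e-6)

    def test_matches_dense_grid_search(self, coarse_grid, random_spatial_instance):
        y, a, rows, cols, prior_mean, prior_sd = random_spatial_instance
        focal = CellIndex(4, 3)
        mu, sig = prior_mean.values[4, 3], prior_sd.values[4, 3]
        s_hat, _ = update_cell(focal, y, a, rows, cols, coarse_grid, mu, sig)
        s_grid = np.linspace(1e-6, 1 - 1e-6, 100_000)
        ll = np.array(
            [local_log_likelihood(s, focal, y, a, rows, cols, coarse_grid, TAU) for s in s_grid[::200]]
        )
        # refine around the coarse grid argmax with the full 1e5-point resolution
        coarse_best = s_grid[::200][np.argmax(ll - (s_grid[::200] - mu) ** 2 / (2 * sig**2))]
        window = (s_grid > coarse_best - 0.02) & (s_grid < coarse_best + 0.02)
        sw = s_grid[window]
        llw = np.array([local_log_likelihood(s, focal, y, a, rows, cols, coarse_grid, TAU) for s in sw])
        best = sw[np.argmax(llw - (sw - mu) ** 2 / (2 * sig**2))]
        assert abs(s_hat - best) <= 2e-5

    def test_diffuse_prior_approaches_weighted_detection_rate(self, coarse_grid, rng):
        # m = d = 1: every present bird is detected, so s_hat ~ weighted mean of y
        n = 4000
        rows, cols = rng.integers(0, 8, n), rng.integers(0, 8, n)
        a = np.full(n, 1.0 - 1e-9)
        y = (rng.random(n) < 0.3).astype(float)
        focal = CellIndex(4, 4)
        s_hat, _ = update_cell(focal, y, a, rows, cols, coarse_grid, 0.5, 10.0)
        d = np.hypot(rows - 4, cols - 4)
        w = np.where(d <= 7.5, np.exp(-TAU * d**2 / 2), 0.0)
        assert s_hat == pytest.approx((w * y).sum() / w.sum(), abs=0.01)

    def test_laplace_sd_positive_at_interior_mode(self, coarse_grid, random_spatial_instance):
        y, a, rows, cols, prior_mean, prior_sd = random_spatial_instance
        s_hat, sd = update_cell(CellIndex(2, 2), y, a, rows, cols, coarse_grid, 0.5, 0.15)
        assert 1e-6 < s_hat < 1 - 1e-6
        assert sd > 0


class TestUpdateRaster:
    def test_agrees_with_per_cell_updates(self, coarse_grid, random_spatial_instance):
        y, a, rows, cols, prior_mean, prior_sd = random_spatial_instance
        post, post_sd = update_raster(y, a, rows, cols, prior_mean, prior_sd)
        for r in range(0, 8, 3):
            for c in range(0, 8, 3):
                s_hat, sd_hat = update_cell(
                    CellIndex(r, c), y, a, rows, cols, coarse_grid,
                    prior_mean.values[r, c], prior_sd.values[r, c],
                )
                assert post.values[r, c] == pytest.approx(s_hat, abs=1e-6)
                assert post_sd.values[r, c] == pytest.approx(sd_hat, abs=1e-6)

    def test_large_tau_uses_focal_cell_only(self, coarse_grid, random_spatial_instance):
        y, a, rows, cols, prior_mean, prior_sd = random_spatial_instance
        focal = CellIndex(5, 5)
        cfg = SpatialUpdateConfig(tau_spatial=100.0, truncation_radius_km=0.4)
        post, _ = update_raster(y, a, rows, cols, prior_mean, prior_sd, cfg)
        keep = (rows == 5) & (cols == 5)
        s_focal, _ = update_cell(
            focal, y[keep], a[keep], rows[keep], cols[keep], coarse_grid,
            prior_mean.values[5, 5], prior_sd.values[5, 5], cfg,
        )
        assert post.values[5, 5] == pytest.approx(s_focal, abs=1e-4)

    def test_tau_zero_gives_one_shared_pooled_map(self, coarse_grid, random_spatial_instance):
        y, a, rows, cols, _, _ = random_spatial_instance
        flat_mu = RasterLayer(coarse_grid, np.full((8, 8), 0.4))
        flat_sd = RasterLayer(coarse_grid, np.full((8, 8), 0.2))
        cfg = SpatialUpdateConfig(tau_spatial=0.0)
        post, _ = update_raster(y, a, rows, cols, flat_mu, flat_sd, cfg)
        assert np.ptp(post.values) < 1e-9

    def test_cell_update_order_independent(self, coarse_grid, random_spatial_instance):
        y, a, rows, cols, prior_mean, prior_sd = random_spatial_instance
        post1, _ = update_raster(y, a, rows, cols, prior_mean, prior_sd)
        post2, _ = update_raster(y, a, rows, cols, prior_mean, prior_sd)
        assert np.array_equal(post1.values, post2.values)


class TestDownsample:
    def test_constant_block(self, fine_grid):
        mean = RasterLayer(fine_grid, np.full((40, 40), 0.42))
        var = RasterLayer(fine_grid, np.full((40, 40), 0.02))
        cm, cv = downsample_prior(mean, var)
        assert np.allclose(cm.values, 0.42)
        assert np.allclose(cv.values, 0.02)

    def test_arithmetic_mean_oracle(self, fine_grid, rng):
        vals = rng.uniform(0, 1, (40, 40))
        cm, _ = downsample_prior(RasterLayer(fine_grid, vals), RasterLayer(fine_grid, vals))
        block = vals[:10, 10:20]
        assert cm.values[0, 1] == pytest.approx(block.sum() / 100.0, abs=1e-12)

    def test_nodata_excluded_from_average(self, fine_grid, rng):
        vals = rng.uniform(0, 1, (40, 40))
        vals[:10, :5] = np.nan  # half of block (0,0)
        cm, _ = downsample_prior(RasterLayer(fine_grid, vals), RasterLayer(fine_grid, vals))
        assert cm.values[0, 0] == pytest.approx(np.nanmean(vals[:10, :10]), abs=1e-12)
        vals[:10, :10] = np.nan
        cm, _ = downsample_prior(RasterLayer(fine_grid, vals), RasterLayer(fine_grid, vals))
        assert np.isnan(cm.values[0, 0])


class TestProbitPriorMoments:
    def test_degenerate_variance(self):
        mean, sd = probit_prior_moments(0.7, 0.0)
        assert mean == pytest.approx(float(ndtr(0.7)), abs=1e-12)
        assert sd == 0.0

    def test_symmetric_case(self):
        mean, _ = probit_prior_moments(0.0, 1.0)
        assert mean == pytest.approx(0.5, abs=1e-10)

    def test_closed_form_mean_oracle(self):
        # E[Phi(Z)] = Phi(mu / sqrt(1 + v)) for Z ~ N(mu, v)
        for mu, v in [(1.0, 0.25), (-0.8, 1.5), (0.3, 0.04)]:
            mean, _ = probit_prior_moments(mu, v)
            assert mean == pytest.approx(float(ndtr(mu / np.sqrt(1 + v))), abs=1e-9)

    def test_monte_carlo_cross_check(self):
        rng = np.random.default_rng(123)
        mu, v = 1.0, 0.25
        z = rng.normal(mu, np.sqrt(v), 10_000_000)
        vals = ndtr(z)
        mean, sd = probit_prior_moments(mu, v)
        assert mean == pytest.approx(float(vals.mean()), abs=2e-3)
        assert sd == pytest.approx(float(vals.std()), abs=2e-3)


class TestUpsample:
    def test_uniform_block_unchanged(self):
        block = np.full(100, 0.3)
        out = upsample_posterior(0.3, block)
        assert out == pytest.approx(block, abs=1e-9)

    def test_matches_brute_force_delta_scan(self, rng):
        prior = rng.uniform(0.05, 0.95, 100)
        coarse = 0.6
        out = upsample_posterior(coarse, prior)
        deltas = np.arange(-8, 8, 1e-4)
        means = ndtr(ndtri(prior)[None, :] + deltas[:, None]).mean(axis=1)
        delta_best = deltas[np.argmin(np.abs(means - coarse))]
        expected = ndtr(ndtri(prior) + delta_best)
        assert np.abs(out - expected).max() <= 2e-4

    def test_mean_consistency_and_rank_preservation(self, rng):
        prior = rng.uniform(0.02, 0.98, 100)
        for coarse in (0.1, 0.45, 0.9):
            out = upsample_posterior(coarse, prior)
            assert out.mean() == pytest.approx(coarse, abs=1e-6)
            assert np.array_equal(np.argsort(out), np.argsort(prior))

    def test_upward_shift_raises_every_cell(self, rng):
        prior = rng.uniform(0.1, 0.5, 100)
        coarse = prior.mean() + 0.2
        out = upsample_posterior(coarse, prior)
        assert (out >= prior).all()

    def test_literal_variant_is_block_constant(self, rng):
        prior = rng.uniform(0.1, 0.9, 100)
        out = upsample_posterior(0.5, prior, literal=True)
        assert np.ptp(out) == 0.0

    def test_raster_blocks(self, fine_grid, rng):
        fine_prior = RasterLayer(fine_grid, rng.uniform(0.05, 0.95, (40, 40)))
        coarse_grid = fine_grid.coarsen(10)
        coarse_post = RasterLayer(coarse_grid, rng.uniform(0.1, 0.9, (4, 4)))
        out = upsample_raster(coarse_post, fine_prior)
        block = out.values[:10, :10]
        assert block.mean() == pytest.approx(coarse_post.values[0, 0], abs=1e-6)
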