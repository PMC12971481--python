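import dataclasses

import numpy as np
import pytest
from scipy.stats import chisquare

from avitwin.core import CellIndex, read_recording_csv, write_recording_csv
from avitwin.core import day_fraction, minute_fraction
from avitwin.posterior_detection import d_mk
from avitwin.prior_detection import DetectionCoefficients, predict_d_pam
from avitwin.prior_migration import MigrationParams, migration_probability
from avitwin.synthetic import (
    ObserverPopulation,
    make_world,
    perturb_prior,
    simulate_mk_stream,
    simulate_pam,
)


def small_world(seed=0, **kw):
    kw.setdefault("field_sigma_cells", 8)
    return make_world(n_species=3, n_rows=40, n_cols=40, seed=seed, **kw)


def _observers(world, n_users=40, seed=1):
    rng = np.random.default_rng(seed)
    homes = tuple(
        CellIndex(int(r), int(c))
        for r, c in zip(rng.integers(0, 40, n_users), rng.integers(0, 40, n_users))
    )
    return ObserverPopulation(home_cells=homes)


class TestMakeWorld:
    def test_same_seed_is_bitwise_identical(self):
        w1, w2 = small_world(3), small_world(3)
        for a, b in zip(w1.species, w2.species):
            assert np.array_equal(a.spatial_field.values, b.spatial_field.values)
            assert a.migration == b.migration
            assert a.detection == b.detection
            assert a.translation == b.translation

    def test_single_species_world(self):
        w = make_world(n_species=1, n_rows=20, n_cols=20, seed=0, field_sigma_cells=4)
        assert len(w.species) == 1
        with pytest.raises(ValueError):
            make_world(n_species=0)

    def test_fields_bounded_and_reproducible_summary(self):
        w = small_world(7)
        for sp in w.species:
            v = sp.spatial_field.values
            assert v.min() >= 0.02 and v.max() <= 0.98
        again = small_world(7)
        for a, b in zip(w.species, again.species):
            assert a.spatial_field.values.mean() == b.spatial_field.values.mean()
            assert a.spatial_field.values.std() == b.spatial_field.values.std()

    def test_migration_parameters_in_realistic_ranges(self):
        w = make_world(n_species=20, n_rows=20, n_cols=20, seed=11, field_sigma_cells=4)
        for sp in w.species:
            if sp.migration.is_migratory:
                arrival60 = sp.migration.spring_mean + 60 * sp.migration.spring_lat_slope
                assert 90 <= arrival60 <= 160

    def test_latitude_mapping_is_affine_north_down(self):
        w = small_world(0)
        lat_top = w.latitude_of_row(0)
        lat_bottom = w.latitude_of_row(39)
        assert lat_top > lat_bottom
        mid = w.latitude_of_row(np.array([10, 20]))
        assert mid[0] > mid[1]


class TestPerturbPrior:
    def test_zero_shift_reproduces_truth(self):
        w = small_world(5)
        priors = perturb_prior(w, 0.0, 0.0, seed=2)
        for sp in w.species:
            b = priors[sp.species_id]
            assert np.allclose(b.fine_mean.values, sp.spatial_field.values, atol=1e-12)
            assert b.migration == sp.migration

    def test_shift_creates_reproducible_gap(self):
        w = small_world(5)
        p1 = perturb_prior(w, 0.5, 3.0, seed=2)
        p2 = perturb_prior(w, 0.5, 3.0, seed=2)
        gaps = []
        for sp in w.species:
            gap = np.abs(p1[sp.species_id].fine_mean.values - sp.spatial_field.values).mean()
            gaps.append(gap)
            assert np.array_equal(
                p1[sp.species_id].fine_mean.values, p2[sp.species_id].fine_mean.values
            )
        assert min(gaps) > 0.0

    def test_prior_sd_layer_is_stated_constant(self):
        w = small_world(5)
        priors = perturb_prior(w, 0.5, 3.0, seed=2)
        b = priors[w.species_ids[0]]
        assert np.allclose(b.coarse_sd.values, 0.15)


class TestSimulatePam:
    def test_silent_species_never_detected(self):
        w = small_world(6)
        mute = dataclasses.replace(
            w.species[0],
            detection=DetectionCoefficients(-40.0, (0.0,) * 4, (0.0,) * 4),
        )
        w2 = dataclasses.replace(w, species=(mute,) + w.species[1:])
        recs = simulate_pam(w2, [CellIndex(5, 5)], range(150, 160), seed=3)
        assert sum(r.detections[0] for r in recs) == 0

    def test_rate_matches_analytic_mean(self):
        w = small_world(6)
        cell = CellIndex(10, 10)
        days = range(150, 181)
        recs = simulate_pam(w, [cell], days, seed=4)
        sp = w.species[1]
        k = 1
        lat = w.latitude_of_row(cell.row)
        probs = []
        for r in recs:
            m = migration_probability(sp.migration, lat, r.timestamp.day_of_year)
            s = sp.spatial_field.values[cell.row, cell.col]
            d = predict_d_pam(
                sp.detection,
                day_fraction(r.timestamp.day_of_year),
                minute_fraction(r.timestamp.minute_of_day),
            )
            probs.append(m * s * d)
        probs = np.asarray(probs)
        observed = sum(r.detections[k] for r in recs)
        expected = probs.sum()
        sd = np.sqrt((probs * (1 - probs)).sum())
        assert abs(observed - expected) <= 3 * sd

    def test_deterministic_given_seed(self):
        w = small_world(6)
        a = simulate_pam(w, [CellIndex(3, 3)], range(150, 153), seed=9)
        b = simulate_pam(w, [CellIndex(3, 3)], range(150, 153), seed=9)
        assert a == b

    def test_station_outside_grid_rejected(self):
        w = small_world(6)
        with pytest.raises(ValueError):
            simulate_pam(w, [CellIndex(100, 0)], range(150, 151), seed=0)


class TestSimulateMkStream:
    def test_deterministic_and_schema_round_trip(self, tmp_path):
        w = small_world(8)
        obs = _observers(w)
        s1 = simulate_mk_stream(w, obs, range(140, 146), seed=5)
        s2 = simulate_mk_stream(w, obs, range(140, 146), seed=5)
        assert np.array_equal(s1.values, s2.values)
        assert s1.recordings == s2.recordings
        path = tmp_path / "stream.csv"
        write_recording_csv(s1, path)
        back = read_recording_csv(path)
        assert back.recordings == s1.recordings
        assert np.array_equal(back.values, s1.values)

    def test_unavailable_species_never_detected(self):
        w = small_world(8)
        gone = dataclasses.replace(
            w.species[0],
            migration=MigrationParams(10_000.0, 0.0, 1.0, 20_000.0, 0.0, 1.0, True),
        )
        w2 = dataclasses.replace(w, species=(gone,) + w.species[1:])
        stream = simulate_mk_stream(w2, _observers(w2), range(140, 150), seed=6)
        assert stream.values[:, 0].sum() == 0

    def test_detection_rate_matches_analytic_expectation(self):
        w = small_world(8)
        stream = simulate_mk_stream(w, _observers(w, n_users=60), range(140, 160), seed=7)
        meta = stream.meta_frame()
        sp = w.species[2]
        day = meta["day_of_year"].to_numpy()
        lat = meta["latitude_deg"].to_numpy()
        dpam = predict_d_pam(
            sp.detection, day_fraction(day), minute_fraction(meta["minute_of_day"].to_numpy())
        )
        dmk = d_mk(
            sp.translation,
            meta["rec_type"].cat.codes.to_numpy(),
            meta["log_duration"].to_numpy(),
            dpam,
        )
        m = migration_probability(sp.migration, lat, day)
        s = sp.spatial_field.values[meta["row"].to_numpy(), meta["col"].to_numpy()]
        p = m * s * dmk
        observed = stream.values[:, 2].sum()
        sd = np.sqrt((p * (1 - p)).sum())
        assert abs(observed - p.sum()) <= 3 * sd

    def test_unbiased_trigger_times_are_uniform(self):
        # b = 0: direct-recording start minutes are uniform over the active window
        w = small_world(8)
        rng = np.random.default_rng(0)
        homes = tuple(
            CellIndex(int(r), int(c))
            for r, c in zip(rng.integers(0, 40, 50), rng.integers(0, 40, 50))
        )
        obs = ObserverPopulation(home_cells=homes, trigger_bias=0.0, type_mix=(1.0, 0.0, 0.0))
        rejections = 0
        for seed in range(20):
            stream = simulate_mk_stream(w, obs, range(150, 157), seed=seed)
            minutes = np.array([r.timestamp.minute_of_day for r in stream.recordings])
            counts, _ = np.histogram(minutes, bins=np.linspace(240, 1320, 10))
            p = chisquare(counts).pvalue
            if p < 0.01:
                rejections += 1
        assert rejections <= 1

    def test_biased_trigger_times_are_not_uniform(self):
        w = small_world(8)
        rng = np.random.default_rng(0)
        homes = tuple(
            CellIndex(int(r), int(c))
            for r, c in zip(rng.integers(0, 40, 80), rng.integers(0, 40, 80))
        )
        obs = ObserverPopulation(home_cells=homes, trigger_bias=25.0, type_mix=(1.0, 0.0, 0.0))
        pvals = []
        for seed in range(5):
            stream = simulate_mk_stream(w, obs, range(150, 160), seed=seed)
            minutes = np.array([r.timestamp.minute_of_day for r in stream.recordings])
            counts, _ = np.histogram(minutes, bins=np.linspace(240, 1320, 10))
            pvals.append(chisquare(counts).pvalue)
        assert min(pvals) < 0.01

    def test_type_mix_validation(self):
        with pytest.raises(ValueError):
            ObserverPopulation(home_cells=(CellIndex(0, 0),), type_mix=(0.5, 0.2, 0.2))
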