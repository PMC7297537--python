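import numpy as np
import pytest

from compassrun.geometry import LocalFrame
from compassrun.synthetic import (SimConfig, simulate_dataset,
                                  simulate_trial, write_dataset)
from compassrun.track_io import read_trial_table


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_trials=3, seed=99)
        a_recs, a_truth = simulate_dataset(cfg)
        b_recs, b_truth = simulate_dataset(cfg)
        for a, b in zip(a_recs, b_recs):
            np.testing.assert_array_equal(a.dog_track.lat, b.dog_track.lat)
            np.testing.assert_array_equal(a.dog_track.lon, b.dog_track.lon)
            np.testing.assert_array_equal(a.owner_track.lat,
                                          b.owner_track.lat)
            assert a.wind_from_deg == b.wind_from_deg
        assert a_truth.equals(b_truth)

    def test_different_seeds_differ(self):
        a, _ = simulate_dataset(SimConfig(n_trials=1, seed=1))
        b, _ = simulate_dataset(SimConfig(n_trials=1, seed=2))
        assert not np.array_equal(a[0].dog_track.lat, b[0].dog_track.lat)


class TestConfigValidation:
    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(p_tracking=0.5, p_scouting=0.5, p_combined=0.5)

    def test_negative_kappa_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(kappa_axial=-1.0)


class TestDrawnConditions:
    def test_high_kappa_concentrates_on_axis(self):
        cfg = SimConfig(n_trials=120, p_tracking=0, p_scouting=1,
                        p_combined=0, kappa_axial=50.0, seed=3)
        _, truth = simulate_dataset(cfg)
        axial_dev = np.minimum(truth["run_azimuth_mag"] % 180,
                               180 - truth["run_azimuth_mag"] % 180)
        assert (axial_dev <= 10.0).mean() >= 0.95

    def test_strategy_counts_near_probabilities(self):
        cfg = SimConfig(n_trials=200, seed=23)
        _, truth = simulate_dataset(cfg)
        counts = truth["strategy"].value_counts()
        # binomial 99 % bounds around (0.60, 0.32, 0.08) x 200
        assert 100 <= counts.get("tracking", 0) <= 140
        assert 47 <= counts.get("scouting", 0) <= 82
        assert 4 <= counts.get("combined", 0) <= 28

    def test_run_lengths_truncated_at_5m(self):
        cfg = SimConfig(n_trials=60, p_tracking=0, p_scouting=1,
                        p_combined=0, run_length_sd=15.0, seed=24)
        _, truth = simulate_dataset(cfg)
        assert (truth["run_length_m"] >= 5.0).all()


class TestEmittedStructure:
    def test_truth_consistent_with_tracks(self, frame):
        cfg = SimConfig(n_trials=5, gps_noise_sigma=0.0, seed=25)
        recs, truth = simulate_dataset(cfg)
        for rec, (_, t) in zip(recs, truth.iterrows()):
            x, y = frame.project(rec.dog_track.lat, rec.dog_track.lon)
            ox, oy = frame.project(rec.owner_track.lat,
                                   rec.owner_track.lon)
            open_i = int(t["open_index"])
            # at the opening fix the separation is at least 100 m
            sep = np.hypot(x[open_i] - ox[open_i], y[open_i] - oy[open_i])
            assert sep >= 100.0
            assert np.hypot(x[open_i - 1] - ox[open_i - 1],
                            y[open_i - 1] - oy[open_i - 1]) < 100.0
            # the owner holds the truth position once frozen
            assert np.hypot(ox[-1] - t["owner_x"],
                            oy[-1] - t["owner_y"]) < 1e-6
            # the dog is stationary at the truth turning fix
            ti = int(t["turning_index"])
            assert np.hypot(x[ti + 1] - x[ti], y[ti + 1] - y[ti]) < 1e-9

    def test_round_trip_through_track_io(self, tmp_path):
        cfg = SimConfig(n_trials=3, seed=26)
        recs, truth = simulate_dataset(cfg)
        out = write_dataset(recs, truth, tmp_path / "ds")
        loaded = read_trial_table(out / "trials.csv")
        assert len(loaded) == 3
        for a, b in zip(loaded, recs):
            assert len(a.dog_track) == len(b.dog_track)
            np.testing.assert_allclose(a.dog_track.lat, b.dog_track.lat,
                                       atol=1e-7)
            np.testing.assert_allclose(a.dog_track.time, b.dog_track.time,
                                       atol=1e-3)
            assert a.declination_deg == b.declination_deg

    def test_sampling_interval_respected(self):
        for dt in (2.5, 5.0):
            cfg = SimConfig(n_trials=1, sampling_interval=dt, seed=27)
            rec, _ = simulate_trial(cfg, 5, "t", "dog01")
            assert np.allclose(np.diff(rec.dog_track.time), dt)


class TestPipelineRecovery:
    def test_azimuth_b_recovered_under_noise(self, frame):
        """At beelines >= 300 m the owner bearing from the turning point
        survives default GPS noise to within ~2 degrees."""
        from compassrun.geometry import circular_difference, true_bearing
        from compassrun.pipeline import analyze_trial

        cfg = SimConfig(n_trials=120, p_tracking=0, p_scouting=1,
                        p_combined=0, seed=55)
        recs, truth = simulate_dataset(cfg)
        tmap = truth.set_index("trial_id")
        errs = []
        for rec in recs:
            x, y = frame.project(rec.dog_track.lat, rec.dog_track.lon)
            for res in analyze_trial(rec, frame):
                row = res["excursion"]
                if row["beeline_m"] < 300:
                    continue
                t = tmap.loc[row["trial_id"]]
                want = true_bearing(x[int(t["turning_index"])],
                                    y[int(t["turning_index"])],
                                    t["owner_x"], t["owner_y"])
                errs.append(abs(circular_difference(row["azimuth_b"],
                                                    want)))
        errs = np.asarray(errs)
        assert len(errs) >= 50
        assert np.median(errs) < 1.0
        assert (errs <= 2.0).mean() >= 0.90

    def test_run_length_recovered_for_resolvable_runs(self, frame):
        """Chord-measured compass-run length is unbiased to within 20 %
        of the generating mean when runs are above the direction-
        resolvability scale (2.5 s fixes, 3 m 2-D RMS noise, gate scaled
        to the receiver accuracy)."""
        from compassrun.config import AnalysisConfig
        from compassrun.pipeline import analyze_trial

        cfg = SimConfig(n_trials=250, p_tracking=0, p_scouting=1,
                        p_combined=0, sampling_interval=2.5,
                        gps_noise_sigma=3.0 / np.sqrt(2),
                        run_length_sd=3.0, seed=33)
        acfg = AnalysisConfig(run_length_as_chord=True,
                              min_heading_chord_m=10.5)
        recs, truth = simulate_dataset(cfg)
        lens = []
        for rec in recs:
            for res in analyze_trial(rec, frame, acfg):
                lens += [s["run_length_m"] for s in res["subtracks"]]
        mean = float(np.mean(lens))
        assert abs(mean - cfg.run_length_mean) <= 0.2 * cfg.run_length_mean

    def test_null_axial_truth_is_uniform(self):
        """kappa=0 generates axially uniform run directions (KS check of
        doubled angles against the uniform distribution)."""
        from scipy import stats

        cfg = SimConfig(n_trials=400, p_tracking=0, p_scouting=1,
                        p_combined=0, kappa_axial=0.0, seed=66)
        _, truth = simulate_dataset(cfg)
        doubled = (2 * truth["run_azimuth_mag"].to_numpy()) % 360 / 360.0
        assert stats.kstest(doubled, "uniform").pvalue > 0.01
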