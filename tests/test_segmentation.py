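import numpy as np
import pytest

from conftest import make_excursion
from compassrun.config import AnalysisConfig
from compassrun.geometry import LocalFrame, PlanarTrack
from compassrun.pipeline import analyze_trial
from compassrun.segmentation import (detect_excursions, locate_turning_point,
                                     locate_turning_trajectory,
                                     segment_profile)
from compassrun.synthetic import SimConfig, simulate_dataset


def _planar(xy, dt=5.0):
    xy = np.asarray(xy, float)
    return PlanarTrack(np.arange(len(xy)) * dt, xy[:, 0], xy[:, 1])


def _stationary_owner(n, dt=5.0):
    return PlanarTrack(np.arange(n) * dt, np.zeros(n), np.zeros(n))


def _out_and_back(peak, wander_path=0.0, step=10.0):
    """Dog path straight north to ``peak`` m, optional extra wandering
    near the far point, then straight back to the origin."""
    ys = list(np.arange(0.0, peak + step, step))
    xs = [0.0] * len(ys)
    x = 0.0
    while wander_path > 0:                       # east-west zigzag at peak
        x = 30.0 if x == 0.0 else 0.0
        xs.append(x)
        ys.append(peak)
        wander_path -= 30.0
    back = list(np.arange(peak - step, -step, -step))
    xs += [x] * len(back)
    ys += back
    xs.append(0.0)
    ys.append(0.0)
    return np.column_stack([xs, ys])


class TestDetectExcursions:
    def test_simple_excursion_detected(self):
        dog = _planar(_out_and_back(150.0, wander_path=300.0))
        excs = detect_excursions(dog, _stationary_owner(len(dog)))
        assert len(excs) == 1
        exc = excs[0]
        assert exc.total_length >= 200.0
        # opens at the first fix at least 100 m from the owner
        assert np.hypot(dog.x[exc.start_index], dog.y[exc.start_index]) >= 100
        # closes within 10 m of the frozen owner position
        end = np.hypot(dog.x[exc.end_index] - exc.owner_pos[0],
                       dog.y[exc.end_index] - exc.owner_pos[1])
        assert end <= 10.0

    def test_below_opening_distance_no_excursion(self):
        dog = _planar(_out_and_back(90.0, wander_path=600.0))
        assert detect_excursions(dog, _stationary_owner(len(dog))) == []

    @pytest.mark.parametrize("wander,kept", [(150.0, True), (30.0, False)])
    def test_minimum_length_rule(self, wander, kept):
        # separation reaches 110 m; total excursion path is ~220 vs ~180 m
        dog = _planar(_out_and_back(110.0, wander_path=wander))
        excs = detect_excursions(dog, _stationary_owner(len(dog)))
        assert (len(excs) == 1) == kept

    def test_unreturned_excursion_discarded(self):
        xy = np.column_stack([np.zeros(40), np.arange(40) * 10.0])
        dog = _planar(xy)                        # leaves and never returns
        assert detect_excursions(dog, _stationary_owner(len(dog))) == []


class TestSegmentProfile:
    def test_constant_speed_uniform_deciles(self):
        xy = np.column_stack([np.zeros(101), np.arange(101) * 10.0])
        exc = make_excursion(xy)
        prof = segment_profile(exc)
        np.testing.assert_allclose(prof.speeds, 2.0, rtol=1e-9)

    def test_pause_makes_its_decile_slowest(self):
        xy = [(0.0, 10.0 * i) for i in range(101)]
        times = list(np.arange(101) * 5.0)
        # 60 s pause wholly inside decile 6 (path position 550 m)
        idx = 55
        xy = xy[:idx] + [xy[idx]] * 12 + xy[idx:]
        times = times[:idx] + [times[idx] + 5 * k for k in range(12)] + \
            [t + 60.0 for t in times[idx:]]
        exc = make_excursion(xy, times=times)
        prof = segment_profile(exc)
        assert int(np.argmin(prof.speeds)) + 1 == 6

    def test_decile_lengths_conserve_total(self):
        rng = np.random.default_rng(5)
        xy = rng.normal(size=(80, 2)).cumsum(axis=0) * 10
        exc = make_excursion(xy)
        prof = segment_profile(exc)
        assert np.diff(prof.boundaries).sum() == \
            pytest.approx(exc.total_length, abs=1e-6)
        durations = np.diff(prof.boundary_times)
        assert (prof.speeds * durations).sum() == \
            pytest.approx(exc.total_length, abs=1e-6)


def _speed_profiled_excursion(decile_speeds):
    """Straight 1000 m north, 10 m fixes, per-decile speeds (m/s)."""
    xy = np.column_stack([np.zeros(101), np.arange(101) * 10.0])
    times = [0.0]
    for i in range(100):
        times.append(times[-1] + 10.0 / decile_speeds[i // 10])
    return make_excursion(xy, times=times)


class TestTurningTrajectory:
    def test_slowest_decile_wins(self):
        speeds = [3, 3, 3, 3, 3, 1, 3, 3, 3, 3]
        exc = _speed_profiled_excursion(speeds)
        prof = segment_profile(exc)
        assert locate_turning_trajectory(prof, exc) == 6

    def test_edge_decile_falls_back_to_second_slowest(self):
        speeds = [1, 3, 3, 3, 3, 3, 2, 3, 3, 3]
        exc = _speed_profiled_excursion(speeds)
        prof = segment_profile(exc)
        assert locate_turning_trajectory(prof, exc) == 7

    def test_double_fallback_uses_distance_rule(self):
        # slowest = decile 1 and second slowest = decile 10 are both edge
        # deciles; among the rest, decile 3 is slower but too close to the
        # start (max distance 300 < median 500), so decile 7 is chosen
        speeds = [1, 3, 2.4, 3, 3, 3, 2.5, 3, 3, 1.5]
        exc = _speed_profiled_excursion(speeds)
        prof = segment_profile(exc)
        assert locate_turning_trajectory(prof, exc) == 7

    def test_long_single_gap_marks_decile_improbable(self):
        speeds = [3.0] * 10
        exc = _speed_profiled_excursion(speeds)
        # insert a 150 s single-fix gap in decile 4 -> slowest but improbable
        t = exc.track.time.copy()
        t[35:] += 150.0
        exc.track.time = t
        prof = segment_profile(exc)
        chosen = locate_turning_trajectory(prof, exc)
        assert chosen != 4


class TestTurningPoint:
    def test_argmin_pair(self):
        # decile 1 of a 4-step track; pair speeds 2.0, 1.5, 0.5, 1.8 m/s
        xy = np.column_stack([np.zeros(5), np.cumsum([0, 10, 10, 10, 10.0])])
        times = np.cumsum([0, 5.0, 10 / 1.5, 20.0, 10 / 1.8])
        exc = make_excursion(xy, times=times)
        cfg = AnalysisConfig(n_segments=1)
        assert locate_turning_point(exc, 1, cfg) == 2

    def test_tie_breaks_to_earliest(self):
        xy = np.column_stack([np.zeros(6), np.arange(6) * 10.0])
        exc = make_excursion(xy)
        cfg = AnalysisConfig(n_segments=1)
        assert locate_turning_point(exc, 1, cfg) == 0


class TestSimulatedRecovery:
    def test_noise_free_turning_point_recovered(self, frame):
        cfg = SimConfig(n_trials=40, gps_noise_sigma=0.0, seed=77)
        records, truth = simulate_dataset(cfg)
        tmap = truth.set_index("trial_id")
        checked = 0
        for rec in records:
            for res in analyze_trial(rec, frame):
                row = res["excursion"]
                want = tmap.loc[row["trial_id"]]["turning_index"]
                assert abs(row["turning_index"] - want) <= 2
                checked += 1
        assert checked >= 35
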