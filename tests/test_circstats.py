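import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from compassrun.circstats import (CircularSample, circular_ci,
                                  dog_level_means, mean_vector, rayleigh_p,
                                  rayleigh_test, rose_bins, watson_u2,
                                  watson_u2_bound, watson_u2_stat)


class TestMeanVector:
    def test_axial_opposite_bearings_coincide(self):
        mv = mean_vector(CircularSample([10.0, 190.0], axial=True))
        assert mv.r == pytest.approx(1.0)
        assert mv.mu == pytest.approx(10.0)
        assert mv.axis == "10/190"

    def test_axial_perpendicular_cancels(self):
        mv = mean_vector(CircularSample([0.0, 90.0], axial=True))
        assert mv.r == pytest.approx(0.0, abs=1e-12)

    def test_angular_closed_form(self):
        # C = (2 + cos90)/3, S = sin90/3 -> mu = atan2(1/3, 2/3), r = ...
        mv = mean_vector(CircularSample([0.0, 0.0, 90.0]))
        assert mv.mu == pytest.approx(26.565, abs=1e-3)
        assert mv.r == pytest.approx(np.hypot(2 / 3, 1 / 3), abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(shift=st.floats(0, 360), axial=st.booleans())
    def test_rotation_equivariance(self, shift, axial):
        rng = np.random.default_rng(12)
        bearings = rng.uniform(0, 360, 25)
        base = rayleigh_test(CircularSample(bearings, axial=axial))
        moved = rayleigh_test(
            CircularSample((bearings + shift) % 360, axial=axial))
        period = 180.0 if axial else 360.0
        d = (moved.mu - base.mu - shift) % period
        assert min(d, period - d) < 1e-6
        assert moved.r == pytest.approx(base.r)
        assert moved.p == pytest.approx(base.p)


class TestRayleigh:
    def test_published_group_level_value(self):
        # 27 dogs with grand mean vector length 0.021 -> p ~ 0.99
        assert rayleigh_p(27, 0.021) == pytest.approx(0.9885, abs=0.001)

    def test_no_clustering_gives_p_one(self):
        assert rayleigh_p(50, 0.0) == 1.0

    def test_series_formula_against_monte_carlo_value(self):
        # direct evaluation of the series formula ...
        assert rayleigh_p(100, 0.3) == pytest.approx(1.046e-4, rel=0.02)
        # ... agrees with a frozen 2e6-replicate Monte Carlo estimate of
        # P(R >= 0.3) under uniformity (1.165e-4) to series-truncation
        # accuracy in this deep tail
        assert rayleigh_p(100, 0.3) == pytest.approx(1.165e-4, rel=0.15)

    def test_monotone_decreasing_in_r(self):
        ps = [rayleigh_p(30, r) for r in np.linspace(0, 0.9, 40)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_degenerate_sample_fully_clustered(self):
        res = rayleigh_test(CircularSample([42.0] * 30))
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(rayleigh_p(30, 1.0))

    def test_axial_von_mises_detected(self):
        rng = np.random.default_rng(13)
        doubled = rng.vonmises(0.0, 2.0, 100)
        bearings = (np.degrees(doubled) / 2) % 180 + \
            180 * rng.integers(0, 2, 100)
        res = rayleigh_test(CircularSample(bearings, axial=True))
        assert res.p < 1e-6
        assert min(res.mu % 180, 180 - res.mu % 180) < 10

    def test_uniform_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(14)
        rejections = 0
        for _ in range(500):
            sample = CircularSample(rng.uniform(0, 360, 30))
            rejections += rayleigh_test(sample).p < 0.05
        assert 0.02 <= rejections / 500 <= 0.08

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            rayleigh_p(30, 1.2)


class TestWatson:
    def test_published_statistic_bound(self):
        assert watson_u2_bound(0.027) == ">0.5"
        assert watson_u2_bound(0.036) == ">0.5"

    def test_standard_critical_value(self):
        # 0.187 is the standard 5 % critical value
        assert watson_u2_bound(0.188) == "<0.05"
        assert watson_u2_bound(0.186) in (">0.5", "<0.1", "<0.2")

    def test_identical_samples_give_zero(self):
        a = CircularSample([10.0, 50, 90, 200, 300, 340, 20, 120])
        res = watson_u2(a, a)
        assert res.u2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_bound == ">0.5"

    def test_separated_von_mises_rejected_by_both_routes(self):
        rng = np.random.default_rng(15)
        a = (np.degrees(rng.vonmises(0.0, 2.0, 50))) % 360
        b = (np.degrees(rng.vonmises(np.pi / 2, 2.0, 50))) % 360
        res = watson_u2(CircularSample(a), CircularSample(b),
                        permutations=999, seed=1)
        assert res.p_bound.startswith("<")
        assert float(res.p_bound[1:]) <= 0.05
        assert res.p_permutation < 0.05

    def test_mixed_axial_angular_rejected(self):
        with pytest.raises(ValueError):
            watson_u2(CircularSample([0.0, 10], axial=True),
                      CircularSample([0.0, 10], axial=False))


class TestCircularCI:
    def test_degenerate_sample_zero_width(self):
        lo, hi = circular_ci(CircularSample([77.0] * 20), seed=0,
                             resamples=200)
        assert lo == pytest.approx(77.0) and hi == pytest.approx(77.0)

    def test_arc_contains_point_estimate(self):
        rng = np.random.default_rng(16)
        s = CircularSample((np.degrees(rng.vonmises(1.0, 3.0, 40))) % 360)
        mv = mean_vector(s)
        lo, hi = circular_ci(s, seed=0, resamples=2000)
        width_lo = (mv.mu - lo) % 360
        width_hi = (hi - mv.mu) % 360
        assert width_lo < 180 and width_hi < 180

    def test_r_zero_is_undefined(self):
        with pytest.raises(ValueError):
            circular_ci(CircularSample([0.0, 90, 180, 270]), seed=0)

    def test_coverage_near_nominal(self):
        rng = np.random.default_rng(17)
        hits = 0
        n_sets = 200
        for _ in range(n_sets):
            s = CircularSample(
                (np.degrees(rng.vonmises(np.radians(40.0), 3.0, 40))) % 360)
            lo, hi = circular_ci(s, seed=0, resamples=500)
            width = (hi - lo) % 360
            hits += (40.0 - lo) % 360 <= width
        assert 0.88 <= hits / n_sets <= 0.99


class TestDogLevelMeans:
    def test_single_bearing_per_dog_is_identity(self):
        out = dog_level_means({"a": [10.0], "b": [250.0]})
        assert sorted(out.bearings.tolist()) == [10.0, 250.0]
        assert out.level == "dog"

    def test_repeated_bearing_mean(self):
        out = dog_level_means({"a": [0.0, 0.0]})
        assert out.bearings.tolist() == [0.0]

    def test_cancelling_dog_excluded(self):
        out = dog_level_means({"a": [0.0, 180.0], "b": [90.0]})
        assert out.bearings.tolist() == [90.0]

    def test_hierarchical_concentration_increases(self):
        rng = np.random.default_rng(18)
        per_dog = {}
        bearings_all = []
        for d in range(27):
            axis = (np.degrees(rng.vonmises(0.0, 4.0, 8)) / 2) % 180
            bearings = axis + 180 * rng.integers(0, 2, 8)
            per_dog[f"dog{d}"] = bearings
            bearings_all.extend(bearings)
        grand = mean_vector(dog_level_means(per_dog, axial=True))
        pooled = mean_vector(CircularSample(bearings_all, axial=True))
        assert grand.r > pooled.r


def test_rose_bins_partition_sample():
    rng = np.random.default_rng(19)
    b = rng.uniform(0, 360, 500)
    counts = rose_bins(b, 5.0)
    assert counts.sum() == 500
    assert len(counts) == 72
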