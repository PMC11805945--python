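"""Circular descriptive statistics, transforms and hypothesis tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from phenoshift.circular import (
    angle_to_doy,
    angular_shift_days,
    circ_mean,
    circ_rank_two_sample,
    circular_median,
    doy_to_angle,
    equal_kappa_test,
    kappa_from_r,
    rayleigh_test,
    shift_days_between_doys,
    watson_williams,
)

from conftest import vonmises_deg


class TestTransforms:
    def test_day_one_maps_to_first_degree_step(self):
        assert doy_to_angle(1) == pytest.approx(360 / 365)

    def test_day_365_closes_the_circle(self):
        assert doy_to_angle(365) == pytest.approx(0.0)

    def test_round_trip_exhaustive(self):
        doys = np.arange(1, 366)
        back = angle_to_doy(doy_to_angle(doys))
        np.testing.assert_allclose(back, doys, atol=1e-9)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            doy_to_angle(0)
        with pytest.raises(ValueError):
            doy_to_angle(366)


class TestCircMean:
    def test_identical_angles_fully_concentrated(self):
        s = circ_mean([10.0, 10.0, 10.0])
        assert s.mu == pytest.approx(10.0)
        assert s.r == pytest.approx(1.0)

    def test_antipodal_pair_is_flagged_undefined(self):
        s = circ_mean([0.0, 180.0])
        assert not s.defined
        assert s.r == pytest.approx(0.0)
        assert math.isnan(s.mu)
        assert s.kappa_hat == 0.0

    def test_symmetric_pair_bisected(self):
        s = circ_mean([0.0, 90.0])
        assert s.mu == pytest.approx(45.0)
        assert s.r == pytest.approx(math.sqrt(2) / 2)

    @given(st.floats(min_value=0.01, max_value=0.999))
    @settings(deadline=None)
    def test_kappa_inversion_is_consistent(self, r):
        k = kappa_from_r(r)
        a1 = special.i1e(k) / special.i0e(k)
        assert a1 == pytest.approx(r, abs=1e-8)

    @given(
        st.lists(st.floats(min_value=0, max_value=359.99), min_size=2, max_size=30),
        st.floats(min_value=-360, max_value=360),
    )
    @settings(deadline=None, max_examples=60)
    def test_rotation_equivariance(self, angles, delta):
        base = circ_mean(angles)
        rotated = circ_mean((np.asarray(angles) + delta) % 360.0)
        assert rotated.r == pytest.approx(base.r, abs=1e-9)
        if base.defined and base.r > 1e-6:
            diff = (rotated.mu - base.mu - delta + 180) % 360 - 180
            assert diff == pytest.approx(0.0, abs=1e-6)

    def test_weighted_mean_repeats_equal_expansion(self):
        s_w = circ_mean([10.0, 60.0], weights=[3.0, 1.0])
        s_e = circ_mean([10.0, 10.0, 10.0, 60.0])
        assert s_w.mu == pytest.approx(s_e.mu)
        assert s_w.r == pytest.approx(s_e.r)


class TestCircularMedian:
    def test_median_of_cluster_near_wrap(self):
        # points straddling New Year; a linear median would be absurd
        med = circular_median([350.0, 355.0, 5.0, 10.0, 0.0])
        assert med == pytest.approx(0.0)


class TestRayleigh:
    def test_perfect_uniformity(self):
        res = rayleigh_test([0.0, 90.0, 180.0, 270.0])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_identical_angles_monte_carlo(self):
        res = rayleigh_test([42.0] * 8, mode="monte_carlo", n_sim=100_000, seed=1)
        assert res.p_value < 0.001

    def test_small_n_asymptotic_refused(self):
        with pytest.raises(ValueError, match="monte_carlo"):
            rayleigh_test([0.0, 10.0])

    def test_concentrated_sample_rejects(self, rng):
        a = vonmises_deg(rng, 120.0, 8.0, 30)
        assert rayleigh_test(a).p_value < 1e-6


class TestWatsonWilliams:
    def test_sample_vs_copy_is_null(self, rng):
        a = vonmises_deg(rng, 100.0, 5.0, 20)
        res = watson_williams(a, a.copy())
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_well_separated_clusters_reject(self, rng):
        a = vonmises_deg(rng, 45.0, 20.0, 20)
        b = vonmises_deg(rng, 135.0, 20.0, 20)
        assert watson_williams(a, b).p_value < 0.001

    def test_linear_limit_matches_anova(self, rng):
        # samples spanning < 5 degrees: the circle is locally a line
        a = 100.0 + rng.uniform(-2, 2, 25)
        b = 101.0 + rng.uniform(-2, 2, 25)
        f_circ = watson_williams(a, b).statistic
        f_lin = stats.f_oneway(a, b).statistic
        assert f_circ == pytest.approx(f_lin, rel=0.01)

    def test_low_concentration_warns(self, rng):
        a = rng.uniform(0, 360, 20)
        b = rng.uniform(0, 360, 20)
        with pytest.warns(UserWarning, match="unreliable"):
            watson_williams(a, b)


class TestEqualKappa:
    def test_sample_vs_itself_is_null(self, rng):
        a = vonmises_deg(rng, 50.0, 4.0, 40)
        res = equal_kappa_test(a, a.copy())
        assert res.p_value > 0.99

    def test_strongly_unequal_concentration_rejects(self, rng):
        rejections = 0
        for _ in range(20):
            a = vonmises_deg(rng, 0.0, 10.0, 100)
            b = vonmises_deg(rng, 0.0, 1.0, 100)
            rejections += equal_kappa_test(a, b).p_value < 0.05
        assert rejections >= 19

    def test_degenerate_zero_dispersion_flagged(self):
        res = equal_kappa_test([5.0] * 10, [5.0] * 10)
        assert res.p_value == 1.0
        assert "degenerate" in res.note


class TestCircRankTwoSample:
    def test_identical_samples_null(self, rng):
        a = vonmises_deg(rng, 200.0, 3.0, 15)
        res = circ_rank_two_sample(a, a.copy(), n_perm=999, seed=0)
        assert res.p_value > 0.5

    def test_disjoint_clusters_extreme(self, rng):
        a = 0.0 + rng.uniform(-5, 5, 15)
        b = 120.0 + rng.uniform(-5, 5, 15)
        res = circ_rank_two_sample(a % 360, b, n_perm=1999, seed=0)
        assert res.p_value <= 0.002

    def test_too_few_permutations_rejected(self, rng):
        a = vonmises_deg(rng, 0.0, 2.0, 10)
        with pytest.raises(ValueError, match="resolution"):
            circ_rank_two_sample(a, a, n_perm=99)

    def test_reproducible_with_seed(self, rng):
        a = vonmises_deg(rng, 10.0, 2.0, 12)
        b = vonmises_deg(rng, 60.0, 2.0, 12)
        r1 = circ_rank_two_sample(a, b, n_perm=999, seed=7)
        r2 = circ_rank_two_sample(a, b, n_perm=999, seed=7)
        assert r1.p_value == r2.p_value


class TestAngularShift:
    def test_printed_community_peak_arithmetic(self):
        # 9 May (day 129) vs 17 April (day 107): a 22-day advance
        assert shift_days_between_doys(129, 107) == pytest.approx(22.0)

    def test_identical_angles_zero(self):
        assert angular_shift_days(100.0, 100.0) == 0.0

    def test_new_year_crossing_shortest_arc(self):
        # day 360 -> day 5 is 10 days later via the short way round
        shift = shift_days_between_doys(360, 5)
        assert abs(shift) == pytest.approx(10.0)
        assert shift < 0  # a delay

    @given(
        st.floats(min_value=0, max_value=360), st.floats(min_value=0, max_value=360)
    )
    def test_antisymmetry_and_bound(self, x, y):
        f, b = angular_shift_days(x, y), angular_shift_days(y, x)
        assert f == pytest.approx(-b, abs=1e-9) or abs(abs(f) - 182.5) < 1e-6
        assert abs(f) <= 182.5 + 1e-9
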