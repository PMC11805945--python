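"""Individual and species phenometrics, decade contrasts, community curves."""

import datetime as dt

import numpy as np
import pytest

from phenoshift.phenometrics import (
    IndividualPhenology,
    ShiftPattern,
    SpeciesDecadePhenology,
    ParameterShift,
    build_community_curve,
    classify_pattern,
    community_mean_peak_shift,
    compare_decades,
    date_to_doy365,
    detect_seasons,
    extract_individual_phenology,
    pool_species_decade,
)


def weekly_dates(start: dt.date, n: int):
    return [start + dt.timedelta(days=7 * i) for i in range(n)]


def make_ind(species, ind, start_doy, end_doy, peak_doy, duration):
    return IndividualPhenology(species, ind, 1986, start_doy, end_doy, peak_doy, duration)


class TestExtract:
    def test_start_end_peak_by_definition(self):
        dates = weekly_dates(dt.date(2020, 3, 1), 4)  # d1, d8, d15, d22
        p = extract_individual_phenology("spA", "i1", dates, [0, 5, 9, 0])
        assert p.start_doy == date_to_doy365(dates[1])
        assert p.end_doy == date_to_doy365(dates[2])
        assert p.peak_doy == date_to_doy365(dates[2])  # max count 9
        assert p.duration_days == 7

    def test_single_positive_census(self):
        dates = weekly_dates(dt.date(2020, 5, 1), 3)
        p = extract_individual_phenology("spA", "i1", dates, [0, 4, 0])
        assert p.start_doy == p.end_doy == p.peak_doy
        assert p.duration_days == 0

    def test_all_zero_series_returns_sentinel(self):
        dates = weekly_dates(dt.date(2020, 5, 1), 5)
        assert extract_individual_phenology("spA", "i1", dates, [0] * 5) is None

    def test_peak_tie_breaks_to_earliest(self):
        dates = weekly_dates(dt.date(2020, 3, 1), 4)
        p = extract_individual_phenology("spA", "i1", dates, [0, 7, 7, 0])
        assert p.peak_doy == date_to_doy365(dates[1])

    def test_wrap_season_duration_across_new_year(self):
        # 20 Dec -> 15 Feb flowering: duration must count across the boundary
        dates = [dt.date(2020, 12, 20) + dt.timedelta(days=7 * i) for i in range(10)]
        counts = [1, 2, 3, 5, 3, 2, 1, 1, 1, 0]
        p = extract_individual_phenology("spA", "i1", dates, counts)
        assert p.duration_days == 56  # 8 positive censuses, 7 days apart
        assert p.start_doy == date_to_doy365(dt.date(2020, 12, 20))

    def test_short_gap_does_not_split_season(self):
        counts = [1, 2, 0, 0, 3, 1]  # 2-census gap < the 3-census separator
        assert detect_seasons(counts) == [(0, 5)]

    def test_long_gap_splits_and_longest_season_wins(self):
        dates = weekly_dates(dt.date(2020, 3, 1), 10)
        counts = [2, 0, 0, 0, 1, 3, 2, 1, 0, 0]  # 1-census season, then 4-census
        p = extract_individual_phenology("spA", "i1", dates, counts)
        assert p.start_doy == date_to_doy365(dates[4])


class TestPooling:
    def test_single_individual_identity(self):
        ind = make_ind("spA", "i1", 100, 130, 110, 30)
        pooled = pool_species_decade([ind], "d1")
        assert pooled.mean_start_doy == pytest.approx(100, abs=1e-9)
        assert pooled.mean_end_doy == pytest.approx(130, abs=1e-9)
        assert pooled.peak_median_doy == pytest.approx(110, abs=1e-9)
        assert pooled.mean_duration_days == 30

    def test_symmetric_pair_of_starts(self):
        inds = [make_ind("spA", "i1", 100, 120, 110, 20),
                make_ind("spA", "i2", 110, 130, 120, 20)]
        pooled = pool_species_decade(inds, "d1")
        assert pooled.mean_start_doy == pytest.approx(105, abs=1e-9)

    def test_wrap_pair_pools_across_new_year(self):
        inds = [make_ind("spA", "i1", 360, 20, 5, 25),
                make_ind("spA", "i2", 5, 30, 15, 25)]
        pooled = pool_species_decade(inds, "d1")
        assert pooled.mean_start_doy == pytest.approx(365.0, abs=1e-6)


class TestPooledProductionPeak:
    def test_earliest_day_of_maximum_total(self):
        from phenoshift.phenometrics import pooled_production_peak

        doys = [100, 107, 114, 100, 107, 114]
        counts = [2, 5, 1, 3, 0, 4]  # totals: 100 -> 5, 107 -> 5, 114 -> 5
        assert pooled_production_peak(doys, counts) == 100

    def test_all_zero_rejected(self):
        from phenoshift.phenometrics import pooled_production_peak

        with pytest.raises(ValueError):
            pooled_production_peak([10, 17], [0, 0])


class TestCommunityCurve:
    def _sp(self, name, s, e):
        return SpeciesDecadePhenology(name, "d1", s, 1.0, e, 1.0, (s + e) / 2, e - s, 5)

    def test_single_species_arc(self):
        curve = build_community_curve([self._sp("a", 100, 110)], "d1")
        assert curve.counts[99:110].tolist() == [1] * 11
        assert curve.counts.sum() == 11

    def test_conservation_identity(self):
        species = [self._sp("a", 100, 110), self._sp("b", 50, 180), self._sp("c", 300, 20)]
        curve = build_community_curve(species, "d1")
        expected = sum(
            (e - s) % 365 + 1 for s, e in [(100, 110), (50, 180), (300, 20)]
        )
        assert curve.counts.sum() == expected

    def test_empty_input_all_zero(self):
        assert build_community_curve([], "d1").counts.sum() == 0


class TestPatternTable:
    def make(self, delta, p):
        return ParameterShift(delta, p, p < 0.05)

    @pytest.mark.parametrize(
        "sd, sp, ed, ep, expected",
        [
            (20, 0.01, 15, 0.01, ShiftPattern.FULL_ADVANCE),
            (20, 0.01, 5, 0.5, ShiftPattern.START_ONLY_ADVANCE),
            (3, 0.8, 15, 0.01, ShiftPattern.END_ONLY_ADVANCE),
            (1, 0.9, -1, 0.9, ShiftPattern.NO_CHANGE),
            (-10, 0.01, 2, 0.7, ShiftPattern.START_DELAY_END_UNCHANGED),
            (-10, 0.01, 12, 0.01, ShiftPattern.START_DELAY_END_ADVANCE),
            (-10, 0.01, -12, 0.01, ShiftPattern.FULL_DELAY),
            (20, 0.01, -12, 0.01, ShiftPattern.OTHER),
        ],
    )
    def test_decision_table(self, sd, sp, ed, ep, expected):
        assert classify_pattern(self.make(sd, sp), self.make(ed, ep)) == expected


class TestCompareDecades:
    def simulate_inds(self, rng, start_mu, end_mu, n, sd=3.0):
        out = []
        for i in range(n):
            s = start_mu + rng.normal(0, sd)
            e = end_mu + rng.normal(0, sd)
            out.append(
                IndividualPhenology("spA", f"i{i}", 1986, int(round(s)) % 365 or 365,
                                    int(round(e)) % 365 or 365,
                                    int(round((s + e) / 2)) % 365 or 365,
                                    int(round(e - s)))
            )
        return out

    def test_injected_full_advance_detected(self, rng):
        ref = self.simulate_inds(rng, 120, 160, 15)
        new = self.simulate_inds(rng, 100, 140, 15)
        cmpres = compare_decades("spA", ref, new, seed=0)
        assert cmpres.pattern == ShiftPattern.FULL_ADVANCE
        assert cmpres.start.delta_days == pytest.approx(20, abs=4)
        assert cmpres.duration.delta_days == pytest.approx(0, abs=5)

    def test_start_delay_end_advance_detected(self, rng):
        # the shrinking-season pattern: later start, earlier end
        ref = self.simulate_inds(rng, 100, 180, 15)
        new = self.simulate_inds(rng, 115, 160, 15)
        cmpres = compare_decades("spA", ref, new, seed=0)
        assert cmpres.pattern == ShiftPattern.START_DELAY_END_ADVANCE
        assert cmpres.duration.delta_days < 0

    def test_insufficient_replication_flagged(self):
        ref = [make_ind("spA", "i1", 100, 120, 110, 20)]
        cmpres = compare_decades("spA", ref, ref)
        assert cmpres.pattern == ShiftPattern.OTHER
        assert np.isnan(cmpres.start.p_value)

    def test_rotation_leaves_pattern_and_pvalues_unchanged(self, rng):
        ref = self.simulate_inds(rng, 120, 160, 12)
        new = self.simulate_inds(rng, 100, 145, 12)
        base = compare_decades("spA", ref, new, seed=3)

        def rot(inds, delta):
            return [
                IndividualPhenology(p.species_id, p.individual_id, p.season_year,
                                    (p.start_doy + delta - 1) % 365 + 1,
                                    (p.end_doy + delta - 1) % 365 + 1,
                                    (p.peak_doy + delta - 1) % 365 + 1,
                                    p.duration_days)
                for p in inds
            ]

        rotated = compare_decades("spA", rot(ref, 50), rot(new, 50), seed=3)
        assert rotated.pattern == base.pattern
        assert rotated.start.delta_days == pytest.approx(base.start.delta_days, abs=1e-6)
        assert rotated.start.p_value == pytest.approx(base.start.p_value, abs=1e-9)
        assert rotated.duration.p_value == pytest.approx(base.duration.p_value, abs=1e-12)


class TestCommunityPeakShift:
    def test_identical_decades_zero_shift(self):
        doys = [50, 100, 150, 200]
        shift, test, *_ = community_mean_peak_shift(doys, doys)
        assert shift == pytest.approx(0.0, abs=1e-9)

    def test_rotation_equivariance_exact(self):
        doys = np.array([60, 90, 120, 150, 210])
        shifted = (doys - 22 - 1) % 365 + 1
        shift, *_ = community_mean_peak_shift(doys, shifted)
        assert shift == pytest.approx(22.0, abs=1e-9)

    def test_weighted_mode_uses_curve_counts(self):
        doys = np.arange(1, 366)
        w1 = np.zeros(365, dtype=int)
        w1[100:130] = 5
        w2 = np.zeros(365, dtype=int)
        w2[80:110] = 5
        shift, test, *_ = community_mean_peak_shift(doys, doys, w1, w2)
        assert shift == pytest.approx(20.0, abs=1e-6)
        assert "per-day species counts" in test.note
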