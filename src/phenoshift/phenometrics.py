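"""From weekly flower counts to phenological summaries and decade contrasts.

The census protocol is weekly counts of open flowers on marked individuals.
This module turns those series into individual-level phenometrics (start,
end, peak, duration of a flowering season), pools them into species-by-decade
summaries using circular statistics, compares the two decades per species
(Watson-Williams for start/end dates, a circular permutation rank test for
the peak, one-way ANOVA for duration), and classifies each species into a
shift pattern (full advance, start-only advance, ...). It also builds the
community flowering curve (number of species in flower per day of year) and
the community-level mean peak shift.

Sign convention, stated in every output header: positive delta = advance
(earlier date) for start/end/peak, and = lengthening for duration.
"""

from __future__ import annotations

import datetime as _dt
import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .circular import (
    YEAR_LENGTH,
    CircularSummary,
    TestResult,
    angular_shift_days,
    circ_mean,
    circ_sd_degrees,
    circular_median,
    doy_to_angle,
    shift_days_between_doys,
    watson_williams,
    circ_rank_two_sample,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftPattern",
    "IndividualPhenology",
    "SpeciesDecadePhenology",
    "ParameterShift",
    "ShiftComparison",
    "CommunityCurve",
    "date_to_doy365",
    "detect_seasons",
    "extract_individual_phenology",
    "pool_species_decade",
    "build_community_curve",
    "compare_decades",
    "classify_pattern",
    "community_mean_peak_shift",
]

#: runs of positive censuses separated by at least this many consecutive
#: zero censuses are treated as distinct flowering seasons
SEASON_GAP_CENSUSES = 3


class ShiftPattern(enum.Enum):
    FULL_ADVANCE = "full_advance"
    START_ONLY_ADVANCE = "start_only_advance"
    END_ONLY_ADVANCE = "end_only_advance"
    NO_CHANGE = "no_change"
    START_DELAY_END_UNCHANGED = "start_delay_end_unchanged"
    START_DELAY_END_ADVANCE = "start_delay_end_advance"
    FULL_DELAY = "full_delay"
    OTHER = "other"


@dataclass(frozen=True)
class IndividualPhenology:
    """Phenometrics of one individual's flowering season.

    Day-of-year values live on the shared 365-day circle (Feb 29 collapsed);
    ``duration_days`` is the true calendar span end - start, so seasons that
    wrap over New Year are handled by construction.
    """

    species_id: str
    individual_id: str
    season_year: int
    start_doy: int
    end_doy: int
    peak_doy: int
    duration_days: int


@dataclass(frozen=True)
class SpeciesDecadePhenology:
    """Pooled phenology of one species in one decade."""

    species_id: str
    decade: str
    mean_start_doy: float
    sd_start_days: float
    mean_end_doy: float
    sd_end_days: float
    peak_median_doy: float
    mean_duration_days: float
    n_individuals: int


@dataclass(frozen=True)
class ParameterShift:
    """Decade contrast for one phenological parameter of one species."""

    delta_days: float  # positive = advance (dates) / lengthening (duration)
    p_value: float
    significant: bool


@dataclass(frozen=True)
class ShiftComparison:
    species_id: str
    start: ParameterShift
    end: ParameterShift
    peak: ParameterShift
    duration: ParameterShift
    pattern: ShiftPattern
    alpha: float


@dataclass(frozen=True)
class CommunityCurve:
    """Per-day-of-year count of species in flower for one decade."""

    decade: str
    counts: np.ndarray  # shape (365,), counts[d-1] = species in flower on doy d


def date_to_doy365(date: _dt.date) -> int:
    """Day of year on the common 365-day circle; Feb 29 merges with Feb 28."""
    doy = date.timetuple().tm_yday
    if date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0):
        if doy >= 60:  # Mar 1 of a leap year is yday 61
            doy -= 1
    return doy


def detect_seasons(counts: np.ndarray) -> list[tuple[int, int]]:
    """Index ranges [first, last] of flowering seasons in a census series.

    A season is a maximal run of censuses with positive counts; runs
    separated by fewer than ``SEASON_GAP_CENSUSES`` consecutive zero
    censuses are merged (a mid-season census that happened to find no open
    flowers does not split the season).
    """
    pos = np.flatnonzero(np.asarray(counts) > 0)
    if pos.size == 0:
        return []
    seasons: list[tuple[int, int]] = []
    run_start = prev = int(pos[0])
    for idx in pos[1:]:
        idx = int(idx)
        if idx - prev - 1 >= SEASON_GAP_CENSUSES:
            seasons.append((run_start, prev))
            run_start = idx
        prev = idx
    seasons.append((run_start, prev))
    return seasons


def extract_individual_phenology(
    species_id: str,
    individual_id: str,
    dates: list[_dt.date],
    counts,
) -> IndividualPhenology | None:
    """Phenometrics of one individual from its census series.

    start = first census date with a positive count, end = the last, peak =
    the census date with the maximum count (ties break to the earliest),
    duration = end - start in days. When several separate seasons occur in
    the window the longest is used. Returns None (a "did not flower"
    sentinel, logged) when every census is zero.
    """
    order = np.argsort(np.asarray(dates, dtype="datetime64[D]"))
    dates = [dates[i] for i in order]
    counts = np.asarray(counts)[order]
    seasons = detect_seasons(counts)
    if not seasons:
        logger.info("individual %s/%s did not flower in this window",
                    species_id, individual_id)
        return None
    first, last = max(seasons, key=lambda ab: (dates[ab[1]] - dates[ab[0]]).days)
    season = slice(first, last + 1)
    season_counts = counts[season]
    season_dates = dates[season]
    peak_idx = int(np.argmax(season_counts))  # argmax returns first maximum
    start_date, end_date = season_dates[0], season_dates[-1]
    return IndividualPhenology(
        species_id=species_id,
        individual_id=individual_id,
        season_year=start_date.year,
        start_doy=date_to_doy365(start_date),
        end_doy=date_to_doy365(end_date),
        peak_doy=date_to_doy365(season_dates[peak_idx]),
        duration_days=(end_date - start_date).days,
    )


def pool_species_decade(
    phenologies: list[IndividualPhenology], decade: str
) -> SpeciesDecadePhenology:
    """Pool individual phenologies of one species within one decade.

    Start and end dates are averaged circularly (with circular SDs reported
    in days); the species peak is the circular median of the individuals'
    peak dates; duration is an arithmetic mean of day spans.
    """
    if not phenologies:
        raise ValueError("no individual phenologies to pool")
    species = phenologies[0].species_id
    days_per_degree = YEAR_LENGTH / 360.0
    start_angles = doy_to_angle(np.array([p.start_doy for p in phenologies], dtype=float))
    end_angles = doy_to_angle(np.array([p.end_doy for p in phenologies], dtype=float))
    peak_angles = doy_to_angle(np.array([p.peak_doy for p in phenologies], dtype=float))
    start = circ_mean(start_angles)
    end = circ_mean(end_angles)
    from .circular import angle_to_doy

    return SpeciesDecadePhenology(
        species_id=species,
        decade=decade,
        mean_start_doy=angle_to_doy(start.mu) if start.defined else float("nan"),
        sd_start_days=circ_sd_degrees(start_angles) * days_per_degree,
        mean_end_doy=angle_to_doy(end.mu) if end.defined else float("nan"),
        sd_end_days=circ_sd_degrees(end_angles) * days_per_degree,
        peak_median_doy=angle_to_doy(circular_median(peak_angles)),
        mean_duration_days=float(np.mean([p.duration_days for p in phenologies])),
        n_individuals=len(phenologies),
    )


def pooled_production_peak(doys, counts) -> int:
    """Alternative species-peak definition: the census day of year at which
    pooled flower production (summed over individuals) is highest.

    The default species peak is the circular median of the individuals' own
    peak dates; this variant instead sums counts across individuals per
    census day and returns the earliest day attaining the maximum. Both are
    defensible readings of "median date of highest flower production"; the
    choice is recorded by whichever function the caller uses.
    """
    totals: dict[int, float] = {}
    for d, c in zip(doys, counts):
        totals[int(d)] = totals.get(int(d), 0.0) + float(c)
    if not totals or max(totals.values()) <= 0:
        raise ValueError("no positive pooled production")
    best = max(totals.values())
    return min(d for d, v in totals.items() if v == best)


def _arc_days(start_doy: int, end_doy: int) -> np.ndarray:
    """Days of year covered by the inclusive start->end arc (wrap-aware)."""
    s, e = int(round(start_doy)), int(round(end_doy))
    s = (s - 1) % YEAR_LENGTH + 1
    e = (e - 1) % YEAR_LENGTH + 1
    if s <= e:
        return np.arange(s, e + 1)
    return np.concatenate([np.arange(s, YEAR_LENGTH + 1), np.arange(1, e + 1)])


def build_community_curve(
    species_phenologies: list[SpeciesDecadePhenology], decade: str
) -> CommunityCurve:
    """Number of species in flower on each day of year.

    A species is in flower on every day of its mean-start -> mean-end arc
    (inclusive, wrap-aware). Species with undefined mean dates are skipped
    with a log entry.
    """
    counts = np.zeros(YEAR_LENGTH, dtype=int)
    for sp in species_phenologies:
        if np.isnan(sp.mean_start_doy) or np.isnan(sp.mean_end_doy):
            logger.warning("species %s has undefined mean dates; skipped from curve",
                           sp.species_id)
            continue
        counts[_arc_days(sp.mean_start_doy, sp.mean_end_doy) - 1] += 1
    return CommunityCurve(decade=decade, counts=counts)


def classify_pattern(
    start: ParameterShift, end: ParameterShift
) -> ShiftPattern:
    """Assign the start/end shift pattern from the two date contrasts.

    The pattern is a pure function of significance and direction of the
    start and end shifts (advance = positive delta).
    """

    def direction(shift: ParameterShift) -> str:
        if not shift.significant or not np.isfinite(shift.p_value):
            return "none"
        return "advance" if shift.delta_days > 0 else "delay"

    table = {
        ("advance", "advance"): ShiftPattern.FULL_ADVANCE,
        ("advance", "none"): ShiftPattern.START_ONLY_ADVANCE,
        ("none", "advance"): ShiftPattern.END_ONLY_ADVANCE,
        ("none", "none"): ShiftPattern.NO_CHANGE,
        ("delay", "none"): ShiftPattern.START_DELAY_END_UNCHANGED,
        ("delay", "advance"): ShiftPattern.START_DELAY_END_ADVANCE,
        ("delay", "delay"): ShiftPattern.FULL_DELAY,
    }
    return table.get((direction(start), direction(end)), ShiftPattern.OTHER)


def compare_decades(
    species_id: str,
    individuals_ref: list[IndividualPhenology],
    individuals_new: list[IndividualPhenology],
    alpha: float = 0.05,
    n_perm: int = 1999,
    seed: int | None = None,
) -> ShiftComparison:
    """Compare one species' phenology between two decades.

    Start and end dates: Watson-Williams F on individual dates. Peak: the
    circular permutation rank test. Duration: one-way ANOVA. Deltas are
    computed from the pooled summaries with the advance-positive /
    lengthening-positive sign convention. With < 2 individuals in either
    decade the comparison is emitted with undefined p-values and pattern
    OTHER.
    """
    if len(individuals_ref) < 2 or len(individuals_new) < 2:
        logger.warning("species %s: insufficient replication (%d vs %d)",
                       species_id, len(individuals_ref), len(individuals_new))
        nanshift = ParameterShift(float("nan"), float("nan"), False)
        return ShiftComparison(species_id, nanshift, nanshift, nanshift, nanshift,
                               ShiftPattern.OTHER, alpha)

    pooled_ref = pool_species_decade(individuals_ref, "ref")
    pooled_new = pool_species_decade(individuals_new, "new")

    def angles(phens, attr):
        return doy_to_angle(np.array([getattr(p, attr) for p in phens], dtype=float))

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # low-concentration warnings logged upstream
        ww_start = watson_williams(angles(individuals_ref, "start_doy"),
                                   angles(individuals_new, "start_doy"))
        ww_end = watson_williams(angles(individuals_ref, "end_doy"),
                                 angles(individuals_new, "end_doy"))
    peak_test = circ_rank_two_sample(angles(individuals_ref, "peak_doy"),
                                     angles(individuals_new, "peak_doy"),
                                     n_perm=n_perm, seed=seed)
    dur_ref = [p.duration_days for p in individuals_ref]
    dur_new = [p.duration_days for p in individuals_new]
    if np.ptp(dur_ref + dur_new) == 0:
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(dur_ref, dur_new).pvalue)

    start = ParameterShift(
        shift_days_between_doys(pooled_ref.mean_start_doy, pooled_new.mean_start_doy),
        ww_start.p_value, ww_start.p_value < alpha)
    end = ParameterShift(
        shift_days_between_doys(pooled_ref.mean_end_doy, pooled_new.mean_end_doy),
        ww_end.p_value, ww_end.p_value < alpha)
    peak = ParameterShift(
        shift_days_between_doys(pooled_ref.peak_median_doy, pooled_new.peak_median_doy),
        peak_test.p_value, peak_test.p_value < alpha)
    duration = ParameterShift(
        pooled_new.mean_duration_days - pooled_ref.mean_duration_days,
        anova_p, anova_p < alpha)

    return ShiftComparison(species_id, start, end, peak, duration,
                           classify_pattern(start, end), alpha)


def community_mean_peak_shift(
    doys_ref,
    doys_new,
    weights_ref=None,
    weights_new=None,
) -> tuple[float, TestResult, CircularSummary, CircularSummary]:
    """Shift of the community mean flowering date between decades.

    Two input conventions are supported and the one used is recorded in the
    returned test's note: per-species dates (unweighted samples), or the
    community curve itself (per-day species counts as integer weights, in
    which case the test sample repeats each day by its count). Returns
    (signed shift in days, Watson-Williams result, summary_ref, summary_new);
    positive shift = the community now flowers earlier.
    """

    def expand(doys, weights):
        d = np.asarray(doys, dtype=float)
        if weights is None:
            return d, "per-species dates"
        w = np.asarray(weights)
        if not np.issubdtype(w.dtype, np.integer):
            raise ValueError("curve weights must be integer species counts")
        return np.repeat(d, w), "per-day species counts"

    sample_ref, mode = expand(doys_ref, weights_ref)
    sample_new, _ = expand(doys_new, weights_new)
    summ_ref = circ_mean(doy_to_angle(sample_ref))
    summ_new = circ_mean(doy_to_angle(sample_new))
    if not (summ_ref.defined and summ_new.defined):
        nan_test = TestResult("watson-williams", float("nan"), float("nan"),
                              note="undefined community mean")
        return float("nan"), nan_test, summ_ref, summ_new
    shift = angular_shift_days(summ_ref.mu, summ_new.mu)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        test = watson_williams(doy_to_angle(sample_ref), doy_to_angle(sample_new))
    test = TestResult(test.method, test.statistic, test.p_value, test.df,
                      test.n_per_group, note=f"input: {mode}", extra=test.extra)
    return shift, test, summ_ref, summ_new
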