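"""Seeded generator of synthetic community-phenology inputs.

Emulates the statistical structure the analysis assumes, with ground truth
exposed for recovery tests: ~51 perennial species censused weekly over two
multi-year observation windows ("decades"), each species flowering once a
season along a unimodal bell curve with individual-level jitter, Poisson
count noise, species-specific decade-2 start advances and duration changes;
a three-station daily climate series with linear trends, a sinusoidal
seasonal cycle and injected missingness; pollinator-guild labels; and a
pure-birth (Yule) tree over the species.

The flowering bell for an individual of species s has expected count
``amplitude * exp(-0.5 ((d - peak)/spread)^2)`` at day-of-year distance
measured on the 365-day circle. The nominal flowering window is the +/- 2
spread arc; a decade-2 start advance of ``shift_days`` with duration change
``duration_change_days`` is injected by moving the peak to
``peak - shift + duration_change/2`` and widening the spread by
``duration_change/4``, so start shifts by ``shift_days`` and end by
``shift_days - duration_change_days`` exactly in expectation.

Everything is a pure function of (spec, seed): the same call gives
byte-identical outputs.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import YEAR_LENGTH
from .io import ClimateDay, CountRecord, GuildEntry

__all__ = [
    "SpeciesSpec",
    "ClimateSpec",
    "CommunitySpec",
    "default_community",
    "generate_counts",
    "generate_guilds",
    "generate_climate",
    "generate_tree_newick",
    "generate_tree",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Ground-truth flowering parameters of one synthetic species."""

    species_id: str
    peak_doy_reference: float  # decade-1 expected peak (day of year)
    spread_days: float  # bell s.d.; nominal season = peak +/- 2 spreads
    amplitude: float  # expected open flowers at the peak
    n_individuals: int
    shift_days: float = 0.0  # decade-2 start advance (positive = earlier)
    duration_change_days: float = 0.0  # positive = longer flowering
    individual_jitter_sd_days: float = 4.0
    agents: frozenset[str] = frozenset()
    wind: bool = False

    def __post_init__(self):
        if self.spread_days <= 0 or self.amplitude <= 0 or self.n_individuals < 1:
            raise ValueError("spread, amplitude must be > 0 and n_individuals >= 1")


@dataclass(frozen=True)
class ClimateSpec:
    """Daily climate generating process: linear trend + seasonal cycle + noise.

    Default bases and trends reproduce a warming lowland Mediterranean
    series: minima warming fastest, a modest mean-temperature rise, and a
    slowly declining winter-concentrated rainfall.
    """

    year_start: int = 1974
    year_end: int = 2022
    n_stations: int = 3
    base_tmin: float = 8.9  # degC at year_start
    base_tmax: float = 24.9
    slope_tmin: float = 0.057  # degC / yr
    slope_tmax: float = 0.019
    seasonal_amp_t: float = 9.0  # degC half-range of the annual cycle
    noise_sd_t: float = 1.5
    station_offset_sd: float = 0.3
    wet_prob_winter: float = 0.45  # daily rain probability at the wet peak
    wet_prob_summer: float = 0.02
    rain_scale_mm: float = 9.0  # mean wet-day rainfall at year_start
    rain_trend_frac: float = -0.009  # fractional change of wet-day scale / yr
    rain_year_sd: float = 0.35  # log-sd of the shared year-to-year rain factor
    missing_frac: float = 0.05


@dataclass(frozen=True)
class CommunitySpec:
    species: tuple[SpeciesSpec, ...]
    census_interval_days: int = 7
    decade1_years: tuple[int, ...] = (1985, 1986)
    decade2_years: tuple[int, ...] = (2020, 2021)
    climate: ClimateSpec = field(default_factory=ClimateSpec)

    def __post_init__(self):
        if set(self.decade1_years) & set(self.decade2_years):
            raise ValueError("decade windows overlap")
        ids = [s.species_id for s in self.species]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate species ids")


_AGENT_POOL = (
    frozenset({"small bees", "medium bees", "big bees"}),
    frozenset({"small bees", "medium bees", "big bees", "hoverflies"}),
    frozenset({"medium bees", "big bees"}),
    frozenset({"small bees"}),
    frozenset({"small bees", "hoverflies"}),
    frozenset({"small bees", "medium bees", "big bees", "hoverflies", "butterflies"}),
    frozenset({"small bees", "medium bees", "big bees", "beeflies"}),
    frozenset({"hoverflies", "flies"}),
    frozenset({"small bees", "wasps"}),
    frozenset({"small bees", "sphingids"}),
    frozenset({"small bees", "medium bees", "big bees", "wasps", "butterflies"}),
)


def default_community(
    n_species: int = 51,
    mean_shift_days: float = 24.0,
    preset_seed: int = 51,
) -> CommunitySpec:
    """The default 51-species community preset.

    Mimics a strongly seasonal Mediterranean shrub community: ~70% of
    species peak between days 60 and 180 (late winter - early summer), the
    rest are summer/autumn bloomers; 9-21 individuals per species; 80% of
    species advance in decade 2 (advances drawn with mean
    ``mean_shift_days``, clipped to 6..92 days), 6% delay, the rest do not
    move; duration changes follow 0.5 * shift plus noise, so stronger
    advances lengthen flowering; four wind-pollinated species; one species
    with a pollinator token shared with no one ("very small flies").

    The preset is itself deterministic (``preset_seed`` fixes the species
    table); data randomness enters only through the generate_* seeds.
    """
    rng = np.random.default_rng(preset_seed)
    n_early = int(round(0.7 * n_species))
    peaks = np.concatenate(
        [
            rng.uniform(60, 180, size=n_early),
            rng.uniform(181, 330, size=n_species - n_early),
        ]
    )
    spreads = rng.uniform(8, 22, size=n_species)
    amplitudes = rng.uniform(15, 120, size=n_species)
    n_ind = rng.integers(9, 22, size=n_species)
    u = rng.random(n_species)
    shifts = np.where(
        u < 0.80,
        np.clip(rng.normal(mean_shift_days, 14, size=n_species), 6, 92),
        np.where(u < 0.86, np.clip(rng.normal(-10, 4, size=n_species), -30, -4), 0.0),
    )
    dur_changes = 0.5 * shifts + rng.normal(0, 5, size=n_species)
    wind_idx = set(rng.choice(n_species, size=4, replace=False).tolist())
    lone_idx = next(i for i in range(n_species) if i not in wind_idx)
    species = []
    for i in range(n_species):
        if i in wind_idx:
            agents, wind = frozenset(), True
        elif i == lone_idx:
            agents, wind = frozenset({"very small flies"}), False
        else:
            agents, wind = _AGENT_POOL[rng.integers(len(_AGENT_POOL))], False
        species.append(
            SpeciesSpec(
                species_id=f"sp{i + 1:02d}",
                peak_doy_reference=float(peaks[i]),
                spread_days=float(spreads[i]),
                amplitude=float(amplitudes[i]),
                n_individuals=int(n_ind[i]),
                shift_days=float(shifts[i]),
                duration_change_days=float(dur_changes[i]),
                agents=agents,
                wind=wind,
            )
        )
    return CommunitySpec(species=tuple(species))


def _census_dates(years: tuple[int, ...], interval: int) -> list[_dt.date]:
    start = _dt.date(min(years), 1, 1)
    end = _dt.date(max(years), 12, 31)
    out = []
    d = start
    while d <= end:
        out.append(d)
        d += _dt.timedelta(days=interval)
    return out


def _circ_delta(doy: np.ndarray, peak: float) -> np.ndarray:
    return (doy - peak + YEAR_LENGTH / 2) % YEAR_LENGTH - YEAR_LENGTH / 2


def generate_counts(
    spec: CommunitySpec, seed: int
) -> tuple[list[CountRecord], pd.DataFrame]:
    """Weekly flower-count records for both decades, plus the truth table.

    Returns (records, truth). The truth table holds one row per species with
    the realised generating parameters and the implied nominal (+/- 2
    spread) start/end/duration per decade.
    """
    rng = np.random.default_rng(seed)
    records: list[CountRecord] = []
    truth_rows = []
    windows = (("d1", spec.decade1_years), ("d2", spec.decade2_years))
    for sp in spec.species:
        pk1, sd1 = sp.peak_doy_reference, sp.spread_days
        pk2 = pk1 - sp.shift_days + sp.duration_change_days / 2.0
        sd2 = max(sd1 + sp.duration_change_days / 4.0, 1.0)
        params = {"d1": (pk1, sd1), "d2": (pk2, sd2)}
        for decade, years in windows:
            peak, sd = params[decade]
            dates = _census_dates(years, spec.census_interval_days)
            doys = np.array(
                [d.timetuple().tm_yday for d in dates], dtype=float
            )
            doys = np.minimum(doys, YEAR_LENGTH)  # fold leap day
            for ind in range(1, sp.n_individuals + 1):
                ind_peak = peak + rng.normal(0.0, sp.individual_jitter_sd_days)
                lam = sp.amplitude * np.exp(
                    -0.5 * (_circ_delta(doys, ind_peak % YEAR_LENGTH) / sd) ** 2
                )
                counts = rng.poisson(lam)
                ind_id = f"{decade}_i{ind:02d}"
                for date, c in zip(dates, counts):
                    records.append(CountRecord(sp.species_id, ind_id, date, int(c)))
        truth_rows.append(
            {
                "species_id": sp.species_id,
                "peak_doy_d1": pk1,
                "peak_doy_d2": pk2 % YEAR_LENGTH,
                "spread_d1": sd1,
                "spread_d2": sd2,
                "start_doy_d1": (pk1 - 2 * sd1) % YEAR_LENGTH,
                "end_doy_d1": (pk1 + 2 * sd1) % YEAR_LENGTH,
                "start_doy_d2": (pk2 - 2 * sd2) % YEAR_LENGTH,
                "end_doy_d2": (pk2 + 2 * sd2) % YEAR_LENGTH,
                "duration_d1": 4 * sd1,
                "duration_d2": 4 * sd2,
                "shift_days": sp.shift_days,
                "duration_change_days": sp.duration_change_days,
                "amplitude": sp.amplitude,
                "n_individuals": sp.n_individuals,
                "wind": sp.wind,
            }
        )
    return records, pd.DataFrame(truth_rows)


def generate_guilds(spec: CommunitySpec) -> list[GuildEntry]:
    return [
        GuildEntry(s.species_id, frozenset(s.agents), s.wind) for s in spec.species
    ]


def generate_climate(spec: ClimateSpec, seed: int) -> list[ClimateDay]:
    """Daily three-station climate records with trend, seasonality, noise and
    missingness.

    Temperatures: tmin and tmax follow their own linear trends plus a shared
    sinusoidal annual cycle (peaking late July) and Gaussian noise; tmean is
    their midpoint, so the tmin <= tmean <= tmax invariant holds by
    construction and the implied tmean trend is the average of the two.
    Rainfall: wet days are Bernoulli with a winter-peaked seasonal
    probability; wet-day amounts are exponential with a slowly drifting
    scale modulated by a shared lognormal year factor — the large
    interannual variability that makes real Mediterranean precipitation
    trends hard to detect. Stations share the signal, with small constant
    offsets, independent noise and independent missingness.
    """
    rng = np.random.default_rng(seed)
    days: list[ClimateDay] = []
    dates = pd.date_range(
        _dt.date(spec.year_start, 1, 1), _dt.date(spec.year_end, 12, 31), freq="D"
    )
    t_years = (dates.year - spec.year_start).to_numpy(dtype=float)
    doy = np.minimum(dates.day_of_year.to_numpy(dtype=float), YEAR_LENGTH)
    season_t = np.cos(2 * np.pi * (doy - 208.0) / YEAR_LENGTH)  # peak ~ Jul 27
    season_rain = 0.5 * (1 - np.cos(2 * np.pi * (doy - 15.0) / YEAR_LENGTH))
    wet_p = spec.wet_prob_summer + (spec.wet_prob_winter - spec.wet_prob_summer) * (
        1 - season_rain
    )
    offsets = rng.normal(0.0, spec.station_offset_sd, size=spec.n_stations)
    n_years = spec.year_end - spec.year_start + 1
    # mean-one lognormal factor per calendar year, shared across stations
    year_factor = rng.lognormal(
        -0.5 * spec.rain_year_sd**2, spec.rain_year_sd, size=n_years
    )[t_years.astype(int)]
    for s in range(spec.n_stations):
        tmin = (
            spec.base_tmin
            + spec.slope_tmin * t_years
            + spec.seasonal_amp_t * season_t
            + offsets[s]
            + rng.normal(0.0, spec.noise_sd_t, size=len(dates))
        )
        tmax = (
            spec.base_tmax
            + spec.slope_tmax * t_years
            + spec.seasonal_amp_t * season_t
            + offsets[s]
            + rng.normal(0.0, spec.noise_sd_t, size=len(dates))
        )
        tmax = np.maximum(tmax, tmin + 0.1)
        tmean = 0.5 * (tmin + tmax)
        scale = spec.rain_scale_mm * year_factor * np.maximum(
            1.0 + spec.rain_trend_frac * t_years, 0.05
        )
        wet = rng.random(len(dates)) < wet_p
        precip = np.where(wet, rng.exponential(scale), 0.0)
        missing = rng.random(len(dates)) < spec.missing_frac
        station_id = f"station{s + 1}"
        for i, date in enumerate(dates):
            if missing[i]:
                days.append(ClimateDay(station_id, date.date(), None, None, None, None))
            else:
                days.append(
                    ClimateDay(
                        station_id,
                        date.date(),
                        round(float(tmin[i]), 3),
                        round(float(tmean[i]), 3),
                        round(float(tmax[i]), 3),
                        round(float(precip[i]), 3),
                    )
                )
    return days


def generate_tree_newick(labels: list[str], seed: int) -> str:
    """Pure-birth (Yule) tree over the given tip labels, unit height.

    Lineages split at exponential waiting times (rate proportional to the
    number of live lineages); after the last split the tips are extended by
    one more mean waiting time and all depths are rescaled so every tip sits
    at distance 1 from the root.
    """
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    nodes = [{"birth": 0.0, "children": []}, {"birth": 0.0, "children": []}]
    root_children = [0, 1]
    active = [0, 1]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = active.pop(int(rng.integers(k)))
        left = {"birth": t, "children": []}
        right = {"birth": t, "children": []}
        nodes.append(left)
        li = len(nodes) - 1
        nodes.append(right)
        ri = len(nodes) - 1
        nodes[idx]["children"] = [li, ri]
        active.extend([li, ri])
    t_end = t + rng.exponential(1.0 / n)
    order = rng.permutation(n)
    tip_labels = iter([labels[i] for i in order])
    scale = 1.0 / t_end

    def render(i: int) -> str:
        node = nodes[i]
        if not node["children"]:
            length = (t_end - node["birth"]) * scale
            return f"{next(tip_labels)}:{length:.10f}"
        li, ri = node["children"]
        split_t = nodes[li]["birth"]
        length = (split_t - node["birth"]) * scale
        return f"({render(li)},{render(ri)}):{length:.10f}"

    return f"({render(root_children[0])},{render(root_children[1])}):0.0;"


def generate_tree(labels: list[str], seed: int):
    """Yule tree as a dendropy Tree (see :func:`generate_tree_newick`)."""
    import dendropy

    return dendropy.Tree.get(
        data=generate_tree_newick(labels, seed),
        schema="newick",
        preserve_underscores=True,
    )
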