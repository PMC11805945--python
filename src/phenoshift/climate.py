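"""Station averaging, seasonal/annual aggregation and linear climate trends.

Daily series from nearby stations are averaged per date (unweighted, over the
stations reporting that date) to minimise gaps, aggregated to annual and
meteorological-season values (winter: Dec-Feb with December assigned to the
winter labelled by the following January's year; spring: Mar-May; summer:
Jun-Aug; autumn: Sep-Nov) — temperatures as means, precipitation as sums —
and ordinary least-squares trends are fitted against calendar year. The
cross-species duration ~ start-shift regression lives here too, as the other
ordinary linear model of the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ClimateDay

logger = logging.getLogger(__name__)

__all__ = [
    "TrendFit",
    "SEASON_OF_MONTH",
    "average_stations",
    "aggregate",
    "linear_trend",
    "trend_table",
    "duration_vs_shift_regression",
]

#: month -> meteorological season
SEASON_OF_MONTH = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

#: an aggregate is emitted only when at least this fraction of its days
#: have data (guards against biased seasonal means from sparse coverage)
MIN_COVERAGE = 0.80

_TEMP_VARS = ("tmin", "tmean", "tmax")


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of an aggregated climate variable (or any y) on year (x)."""

    slope: float
    intercept: float
    p_value: float
    r_squared: float
    n: int
    slope_se: float = float("nan")


def average_stations(days: list[ClimateDay]) -> pd.DataFrame:
    """Collapse per-station records to one daily series.

    Per date and variable: unweighted mean over the stations reporting that
    value. Returns a DataFrame indexed by date with columns tmin, tmean,
    tmax, precip (NaN where no station reported).
    """
    if not days:
        raise ValueError("no climate records")
    df = pd.DataFrame(
        {
            "date": [d.date for d in days],
            "tmin": [d.tmin for d in days],
            "tmean": [d.tmean for d in days],
            "tmax": [d.tmax for d in days],
            "precip": [d.precip for d in days],
        }
    )
    out = df.groupby("date")[["tmin", "tmean", "tmax", "precip"]].mean()
    out.index = pd.to_datetime(out.index)
    return out.sort_index()


def aggregate(daily: pd.DataFrame, scope: str = "annual") -> pd.DataFrame:
    """Annual or seasonal aggregates of a daily series.

    scope: "annual" or one of winter/spring/summer/autumn. Temperatures are
    averaged, precipitation is summed. December belongs to the following
    year's winter ("winter 2020" = Dec 2019 + Jan/Feb 2020). Years whose
    scope has less than ``MIN_COVERAGE`` of days observed for a variable get
    a missing aggregate (logged).

    Returns a DataFrame indexed by year with columns tmin, tmean, tmax,
    precip.
    """
    if scope != "annual" and scope not in set(SEASON_OF_MONTH.values()):
        raise ValueError(f"unknown scope {scope!r}")
    df = daily.copy()
    months = df.index.month
    if scope == "annual":
        df["agg_year"] = df.index.year
        keep = np.ones(len(df), dtype=bool)
        expected = np.where(_is_leap(df["agg_year"].to_numpy()), 366, 365)
    else:
        season = np.array([SEASON_OF_MONTH[m] for m in months])
        year = df.index.year.to_numpy().copy()
        year[months == 12] += 1  # December -> following winter
        df["agg_year"] = year
        keep = season == scope
        expected = np.full(len(df), {"winter": 90, "spring": 92,
                                     "summer": 92, "autumn": 91}[scope])
    sub = df.loc[keep]
    expected_days = dict(zip(sub["agg_year"], expected[keep]))
    rows = {}
    for year, grp in sub.groupby("agg_year"):
        exp = expected_days[year]
        row = {}
        for var in _TEMP_VARS:
            vals = grp[var].dropna()
            row[var] = float(vals.mean()) if len(vals) >= MIN_COVERAGE * exp else np.nan
        pr = grp["precip"].dropna()
        row["precip"] = float(pr.sum()) if len(pr) >= MIN_COVERAGE * exp else np.nan
        if any(np.isnan(v) for v in row.values()):
            logger.info("year %s scope %s: sparse coverage, some aggregates missing",
                        year, scope)
        rows[year] = row
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def _is_leap(years: np.ndarray) -> np.ndarray:
    return (years % 4 == 0) & ((years % 100 != 0) | (years % 400 == 0))


def linear_trend(years, values) -> TrendFit:
    """OLS of an aggregate on calendar year; two-sided p on the slope."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(years, dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 years with data")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in year")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n=int(x.size),
        slope_se=float(model.bse[1]),
    )


def trend_table(daily: pd.DataFrame) -> pd.DataFrame:
    """Trend fits for every variable x scope combination.

    Returns a tidy DataFrame (variable, scope, slope, p_value, r_squared, n);
    combinations with too few usable years are skipped with a log entry.
    """
    records = []
    for scope in ("annual", "winter", "spring", "summer", "autumn"):
        agg = aggregate(daily, scope)
        for var in ("tmean", "tmin", "tmax", "precip"):
            try:
                fit = linear_trend(agg.index.to_numpy(), agg[var].to_numpy())
            except ValueError:
                logger.info("trend %s/%s skipped: insufficient data", var, scope)
                continue
            records.append(
                {"variable": var, "scope": scope, "slope": fit.slope,
                 "intercept": fit.intercept, "p_value": fit.p_value,
                 "r_squared": fit.r_squared, "n_years": fit.n}
            )
    return pd.DataFrame.from_records(records)


def duration_vs_shift_regression(start_shift_days, duration_change_days) -> TrendFit:
    """OLS of per-species duration change on start-date shift.

    Both predictors follow the advance-positive / lengthening-positive sign
    convention, so a positive slope means species that advanced more also
    lengthened their flowering more.
    """
    x = np.asarray(start_shift_days, dtype=float)
    y = np.asarray(duration_change_days, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 species")
    if np.ptp(x) == 0:
        raise ValueError("degenerate: no variance in start shift")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return TrendFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        p_value=float(model.pvalues[1]),
        r_squared=float(model.rsquared),
        n=int(x.size),
        slope_se=float(model.bse[1]),
    )
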