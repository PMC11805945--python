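"""Circular statistics for calendar-date samples.

Flowering dates recur on an annual cycle, so date samples live on a circle:
day-of-year ``d`` maps to the angle ``d * 360 / 365`` degrees and all
descriptive and inferential statistics respect the wrap-around at New Year.
Feb 29 is collapsed onto day 59 so every year shares one 365-day circle.

The module provides the date<->angle transforms, the circular mean / resultant
length / concentration summary, and four two-decade hypothesis tests:

* :func:`rayleigh_test` — uniformity against a unimodal (seasonal) alternative,
* :func:`watson_williams` — equality of two mean directions,
* :func:`equal_kappa_test` — equality of two concentrations,
* :func:`circ_rank_two_sample` — a permutation rank-sum test on circular ranks
  for a location difference that does not assume von Mises shape.

All angles are degrees in [0, 360); all tests return a :class:`TestResult`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "CircularSummary",
    "TestResult",
    "doy_to_angle",
    "angle_to_doy",
    "circ_mean",
    "circ_sd_degrees",
    "circular_median",
    "kappa_from_r",
    "rayleigh_test",
    "watson_williams",
    "equal_kappa_test",
    "circ_rank_two_sample",
    "angular_shift_days",
    "shift_days_between_doys",
]

YEAR_LENGTH = 365

#: resultant lengths below this are treated as "no preferred direction"
_R_UNDEFINED_TOL = 1e-12


@dataclass(frozen=True)
class CircularSummary:
    """Descriptive summary of a circular sample.

    Attributes
    ----------
    mu : float
        Mean angle in degrees [0, 360). Meaningless when ``defined`` is False.
    r : float
        Mean resultant length in [0, 1]; 0 = no concentration, 1 = all angles
        identical.
    kappa_hat : float
        Von Mises concentration estimate obtained by inverting A1(kappa) = r.
    n : int
        Sample size.
    defined : bool
        False when r is numerically zero and the mean direction is undefined
        (e.g. an antipodal pair). Consumers must check this flag; mu is set to
        nan in that case rather than silently propagating a number.
    """

    mu: float
    r: float
    kappa_hat: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class TestResult:
    """Outcome of a circular hypothesis test."""

    method: str
    statistic: float
    p_value: float
    df: tuple[float, float] | None = None
    n_per_group: tuple[int, ...] = ()
    note: str = ""
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# transforms


def doy_to_angle(doy, year_length: int = YEAR_LENGTH):
    """Map day-of-year (1..year_length) to degrees on the annual circle.

    ``angle = doy * 360 / year_length`` reduced modulo 360, so day 365 and
    day 0 coincide at 0 degrees.
    """
    d = np.asarray(doy, dtype=float)
    if np.any((d < 1) | (d > year_length)):
        raise ValueError(f"day-of-year outside 1..{year_length}")
    out = np.mod(d * 360.0 / year_length, 360.0)
    return float(out) if np.isscalar(doy) else out


def angle_to_doy(angle, year_length: int = YEAR_LENGTH):
    """Inverse of :func:`doy_to_angle`; 0 degrees maps back to day 365."""
    a = np.mod(np.asarray(angle, dtype=float), 360.0)
    d = a * year_length / 360.0
    d = np.where(d < 0.5, d + year_length, d)  # 0 deg == day 365
    return float(d) if np.isscalar(angle) else d


# ---------------------------------------------------------------------------
# descriptive


def _resultant(angles_deg, weights=None):
    """Return (n_eff, R, mean_cos, mean_sin) for a weighted angle sample."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValueError("empty circular sample")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != a.shape:
            raise ValueError("weights shape mismatch")
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    sw = w.sum()
    c = float(np.sum(w * np.cos(a)) / sw)
    s = float(np.sum(w * np.sin(a)) / sw)
    return sw, math.hypot(c, s), c, s


def kappa_from_r(r: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Invert the von Mises mean-resultant relation A1(kappa) = r.

    Starts from Fisher's piecewise approximation and polishes by Newton
    iteration on A1(kappa) = I1(kappa)/I0(kappa), using the exponentially
    scaled Bessel functions for numerical stability. r = 0 gives kappa = 0;
    r -> 1 diverges and is capped where A1 is numerically 1.
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError("r outside [0, 1]")
    if r < _R_UNDEFINED_TOL:
        return 0.0
    if r > 1.0 - 1e-12:
        return 1e12
    # Fisher (1993) starting values
    if r < 0.53:
        k = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        k = 1.0 / (r**3 - 4 * r**2 + 3 * r)
    for _ in range(max_iter):
        a1 = special.i1e(k) / special.i0e(k)
        # d/dk A1 = 1 - A1/k - A1^2
        deriv = 1.0 - a1 / k - a1 * a1
        if deriv <= 0:
            break
        step = (a1 - r) / deriv
        k_new = k - step
        if k_new <= 0:
            k_new = k / 2.0
        if abs(k_new - k) < tol * max(1.0, k):
            k = k_new
            break
        k = k_new
    return float(max(k, 0.0))


def circ_mean(angles_deg, weights=None) -> CircularSummary:
    """Circular mean direction and resultant length of an angle sample.

    The mean angle is ``atan2`` of the summed sines and cosines (weighted if
    weights are given); ``r`` is the mean resultant length. When r is
    numerically zero the mean direction does not exist and the summary is
    returned with ``defined=False`` and ``mu=nan``.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = int(a.size)
    _, r, c, s = _resultant(a, weights)
    if r < _R_UNDEFINED_TOL:
        return CircularSummary(mu=float("nan"), r=0.0, kappa_hat=0.0, n=n, defined=False)
    mu = math.degrees(math.atan2(s, c)) % 360.0
    return CircularSummary(mu=mu, r=min(r, 1.0), kappa_hat=kappa_from_r(min(r, 1.0)), n=n)


def circ_sd_degrees(angles_deg, weights=None) -> float:
    """Circular standard deviation sqrt(-2 ln r), reported in degrees."""
    _, r, _, _ = _resultant(angles_deg, weights)
    if r < _R_UNDEFINED_TOL:
        return float("inf")
    if r >= 1.0:
        return 0.0
    return math.degrees(math.sqrt(-2.0 * math.log(r)))


def circular_median(angles_deg) -> float:
    """Circular median: the sample angle minimising total arc distance.

    Candidates are restricted to observed angles; ties break to the smallest
    angle, making the estimate deterministic.
    """
    a = np.mod(np.asarray(angles_deg, dtype=float), 360.0)
    if a.size == 0:
        raise ValueError("empty sample")
    diffs = np.abs((a[None, :] - a[:, None] + 180.0) % 360.0 - 180.0)
    totals = diffs.sum(axis=1)
    order = np.lexsort((a, totals))
    return float(a[order[0]])


# ---------------------------------------------------------------------------
# tests


def rayleigh_test(
    angles_deg,
    weights=None,
    mode: str = "asymptotic",
    n_sim: int = 100_000,
    seed: int | None = None,
) -> TestResult:
    """Rayleigh test of circular uniformity.

    Statistic Z = n r^2. The asymptotic p-value uses the classical
    series approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with R = n r,
    accurate for n >= ~10. ``mode="monte_carlo"`` draws ``n_sim`` uniform
    samples of the same size and reports the exceedance fraction of Z
    (with the +1 continuity correction); use it for small n.
    """
    a = np.asarray(angles_deg, dtype=float)
    n = int(a.size)
    _, r, _, _ = _resultant(a, weights)
    big_r = n * r
    z = n * r * r
    if mode == "asymptotic":
        if n < 3:
            raise ValueError("n < 3: use mode='monte_carlo'")
        p = math.exp(math.sqrt(1 + 4 * n + 4 * (n * n - big_r * big_r)) - (1 + 2 * n))
        p = min(max(p, 0.0), 1.0)
        return TestResult("rayleigh", z, p, df=None, n_per_group=(n,))
    if mode == "monte_carlo":
        rng = np.random.default_rng(seed)
        ang = rng.uniform(0.0, 2.0 * math.pi, size=(n_sim, n))
        c = np.cos(ang).mean(axis=1)
        s = np.sin(ang).mean(axis=1)
        z_sim = n * (c * c + s * s)
        p = (1.0 + np.count_nonzero(z_sim >= z)) / (n_sim + 1.0)
        return TestResult("rayleigh-mc", z, float(p), df=None, n_per_group=(n,),
                          extra={"n_sim": n_sim})
    raise ValueError(f"unknown mode {mode!r}")


#: pooled mean resultant length below which the Watson-Williams F
#: concentration correction is unreliable (Batschelet's validity guideline)
WW_RBAR_WARN = 0.45


def watson_williams(a_deg, b_deg) -> TestResult:
    """Watson-Williams F-test for equality of two circular mean directions.

    F = g (N-2) (R1 + R2 - R) / (N - R1 - R2) with the concentration
    correction g = 1 + 3/(8 kappa_hat), kappa_hat estimated from the mean of
    the within-group resultant lengths; p from F(1, N-2). Valid for
    reasonably concentrated samples — a warning (not an error) is issued when
    the pooled within-group mean resultant length falls below
    ``WW_RBAR_WARN``.
    """
    a = np.asarray(a_deg, dtype=float)
    b = np.asarray(b_deg, dtype=float)
    n1, n2 = int(a.size), int(b.size)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    big_n = n1 + n2
    _, r1, _, _ = _resultant(a)
    _, r2, _, _ = _resultant(b)
    r1n, r2n = n1 * r1, n2 * r2
    _, rp, _, _ = _resultant(np.concatenate([a, b]))
    rpn = big_n * rp
    rbar_w = (r1n + r2n) / big_n
    if rbar_w < WW_RBAR_WARN:
        warnings.warn(
            f"Watson-Williams: pooled within-group resultant {rbar_w:.3f} < "
            f"{WW_RBAR_WARN}; the F approximation may be unreliable",
            stacklevel=2,
        )
    denom = big_n - r1n - r2n
    if denom <= 1e-12:
        # every angle identical within groups and across: no dispersion to test
        return TestResult("watson-williams", 0.0, 1.0, df=(1, big_n - 2),
                          n_per_group=(n1, n2), note="degenerate: zero dispersion")
    kappa = kappa_from_r(min(rbar_w, 1.0))
    g = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    f_stat = g * (big_n - 2) * (r1n + r2n - rpn) / denom
    f_stat = max(f_stat, 0.0)
    p = float(stats.f.sf(f_stat, 1, big_n - 2))
    return TestResult("watson-williams", float(f_stat), p, df=(1, big_n - 2),
                      n_per_group=(n1, n2), extra={"rbar_within": rbar_w})


def _equal_kappa_statistic(groups):
    """Chi-square statistic of the concentration-homogeneity test.

    Implements the classical r-bar-range-dependent scheme (Fisher's piecewise
    variance-stabilising transforms; Bartlett-type variant at high
    concentration) for k groups; here k = 2.
    """
    ns = np.array([g.size for g in groups], dtype=float)
    rs = np.array([_resultant(g)[1] for g in groups])
    big_rs = ns * rs
    big_n = ns.sum()
    rbar_all = _resultant(np.concatenate(groups))[1]
    k = len(groups)
    if rbar_all < 0.45:
        g1 = np.arcsin(np.clip(np.sqrt(3.0 / 8.0) * 2.0 * rs, -1.0, 1.0))
        ws = 4.0 * (ns - 4.0) / 3.0
        ws = np.maximum(ws, 1e-8)
        stat = float(np.sum(ws * g1**2) - np.sum(ws * g1) ** 2 / np.sum(ws))
    elif rbar_all < 0.70:
        g2 = np.arcsinh((rs - 1.089) / 0.258)
        ws = (ns - 3.0) / 0.798
        stat = float(np.sum(ws * g2**2) - np.sum(ws * g2) ** 2 / np.sum(ws))
    else:
        vs = ns - 1.0
        ds = np.maximum(ns - big_rs, 1e-12)
        v = big_n - k
        d = ds.sum()
        correction = 1.0 + (np.sum(1.0 / vs) - 1.0 / v) / (3.0 * (k - 1))
        stat = float((v * math.log(d / v) - np.sum(vs * np.log(ds / vs))) / correction)
    return max(stat, 0.0), float(rbar_all)


def equal_kappa_test(a_deg, b_deg) -> TestResult:
    """Two-sample test for equality of circular concentration (dispersion).

    Uses the standard piecewise scheme keyed on the pooled mean resultant
    length r-bar: a variance-stabilised arcsine transform for diffuse data
    (r-bar < 0.45), an arcsinh transform for the mid range, and a
    Bartlett-type statistic at high concentration (r-bar > 0.70). The
    statistic is referred to chi-square with 1 df.
    """
    a = np.asarray(a_deg, dtype=float)
    b = np.asarray(b_deg, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    note = ""
    if np.allclose(a, a.flat[0]) and np.allclose(b, b.flat[0]):
        return TestResult("equal-kappa", 0.0, 1.0, df=(1, float("nan")),
                          n_per_group=(a.size, b.size),
                          note="degenerate: both samples have zero dispersion")
    stat, rbar = _equal_kappa_statistic([a, b])
    p = float(stats.chi2.sf(stat, 1))
    return TestResult("equal-kappa", stat, p, df=(1, float("nan")),
                      n_per_group=(int(a.size), int(b.size)), note=note,
                      extra={"rbar_pooled": rbar})


def _circular_ranks(pooled_deg, origin_deg):
    """Ranks of pooled angles walking the circle from the given origin."""
    rel = np.mod(np.asarray(pooled_deg, dtype=float) - origin_deg, 360.0)
    # average ranks for ties, matching the ordinary rank-sum convention
    return stats.rankdata(rel)


def circ_rank_two_sample(
    a_deg, b_deg, n_perm: int = 1999, seed: int | None = None
) -> TestResult:
    """Permutation rank-sum test for a circular location difference.

    The pooled sample is re-origined at its circular median, angles are
    ranked along the circle from that origin, and the Wilcoxon rank-sum
    statistic of the first sample is compared with its label-permutation
    distribution (two-sided, with the +1 correction). Seeded and
    reproducible; ``n_perm`` must allow the requested resolution
    (>= 999).
    """
    a = np.asarray(a_deg, dtype=float)
    b = np.asarray(b_deg, dtype=float)
    n1, n2 = int(a.size), int(b.size)
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    if n_perm < 999:
        raise ValueError("n_perm < 999 gives too coarse a p-value resolution")
    pooled = np.concatenate([a, b])
    origin = circular_median(pooled)
    ranks = _circular_ranks(pooled, origin)
    w_obs = float(ranks[:n1].sum())
    expect = n1 * (n1 + n2 + 1) / 2.0
    dev_obs = abs(w_obs - expect)
    rng = np.random.default_rng(seed)
    n = n1 + n2
    # vectorised label permutation: argsort of uniforms = random permutation
    count = 0
    block = 512
    done = 0
    while done < n_perm:
        m = min(block, n_perm - done)
        perm = np.argsort(rng.random((m, n)), axis=1)[:, :n1]
        w_perm = ranks[perm].sum(axis=1)
        count += int(np.count_nonzero(np.abs(w_perm - expect) >= dev_obs - 1e-9))
        done += m
    p = (count + 1.0) / (n_perm + 1.0)
    return TestResult("circular rank-sum (permutation)", w_obs, float(p),
                      n_per_group=(n1, n2),
                      extra={"n_perm": n_perm, "origin_deg": origin})


def angular_shift_days(
    mu_ref: float, mu_new: float, year_length: int = YEAR_LENGTH
) -> float:
    """Signed shortest-arc shift between two mean dates, in days.

    Positive = advance (the new date is earlier than the reference); the
    shortest arc is taken, so |shift| <= year_length / 2 and crossing New
    Year is handled (e.g. day 360 -> day 5 is a 10-day delay, not 355).
    """
    delta_deg = (mu_ref - mu_new + 180.0) % 360.0 - 180.0
    return delta_deg * year_length / 360.0


def shift_days_between_doys(
    doy_ref: float, doy_new: float, year_length: int = YEAR_LENGTH
) -> float:
    """Signed advance in days between two (possibly fractional) days-of-year,
    by the shortest arc; positive = the new date is earlier."""
    return (doy_ref - doy_new + year_length / 2.0) % year_length - year_length / 2.0
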