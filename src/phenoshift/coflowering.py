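"""Co-flowering overlap matrices, the decade-change matrix, and reassembly
bookkeeping.

Co-flowering of a focal species with another is the number of days their
flowering arcs overlap divided by the focal species' own flowering days, so
the matrix is asymmetric but obeys the reciprocity identity
``entry(f, o) * days(f) == entry(o, f) * days(o) == shared days`` exactly in
integer arithmetic. The decade-change matrix divides the later decade's
proportion by the earlier one's, encodes decreases with a negative sign
(0.4 -> 0.2 gives -0.5), and marks pairs that gained or lost any overlap as
GAIN / LOSS. A ternary reduction (+1 increased / -1 decreased / 0 unchanged)
restricted to species pairs sharing main pollinators summarises potential
competitive pressure, and rank-order change tracks the reshuffling of the
community's flowering sequence.

Day counting is inclusive: a species flowering on days 10..20 has 11
flowering days; the same convention is applied to the overlap numerator so
proportions are scale-consistent.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import YEAR_LENGTH
from .io import GuildEntry
from .phenometrics import SpeciesDecadePhenology

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeKind",
    "FloweringInterval",
    "ChangeCell",
    "CompetitorSummary",
    "interval_from_phenology",
    "interval_overlap_days",
    "coflowering_matrix",
    "change_cell",
    "change_matrix",
    "count_change_categories",
    "ternary_reduce",
    "ternary_matrix",
    "shared_pollinator_mask",
    "competitor_summary",
    "rank_order_change",
]


class ChangeKind(enum.Enum):
    FOLD = "fold"
    GAIN = "gain"
    LOSS = "loss"
    NONE = "none"


@dataclass(frozen=True)
class FloweringInterval:
    """Inclusive day-of-year arc during which a species is in flower."""

    species_id: str
    start_doy: int
    end_doy: int

    def __post_init__(self):
        for v in (self.start_doy, self.end_doy):
            if not 1 <= v <= YEAR_LENGTH:
                raise ValueError(f"day-of-year {v} outside 1..{YEAR_LENGTH}")

    @property
    def wraps(self) -> bool:
        return self.end_doy < self.start_doy

    @property
    def flowering_days(self) -> int:
        """Inclusive day count of the arc (days 10..20 -> 11 days)."""
        if self.wraps:
            return YEAR_LENGTH - self.start_doy + 1 + self.end_doy
        return self.end_doy - self.start_doy + 1

    def day_set(self) -> frozenset[int]:
        """Explicit set of covered days; the oracle-friendly representation."""
        if self.wraps:
            return frozenset(range(self.start_doy, YEAR_LENGTH + 1)) | frozenset(
                range(1, self.end_doy + 1)
            )
        return frozenset(range(self.start_doy, self.end_doy + 1))


def interval_from_phenology(sp: SpeciesDecadePhenology) -> FloweringInterval:
    """Species decade interval from pooled mean start/end dates (rounded)."""
    s = (int(round(sp.mean_start_doy)) - 1) % YEAR_LENGTH + 1
    e = (int(round(sp.mean_end_doy)) - 1) % YEAR_LENGTH + 1
    return FloweringInterval(sp.species_id, s, e)


def _segments(iv: FloweringInterval) -> list[tuple[int, int]]:
    """Arc as 1 or 2 linear [lo, hi] segments on 1..365."""
    if iv.wraps:
        return [(iv.start_doy, YEAR_LENGTH), (1, iv.end_doy)]
    return [(iv.start_doy, iv.end_doy)]


def interval_overlap_days(a: FloweringInterval, b: FloweringInterval) -> int:
    """Days both species are in flower: the intersection of two circular
    arcs with inclusive counting. Symmetric by construction."""
    total = 0
    for lo1, hi1 in _segments(a):
        for lo2, hi2 in _segments(b):
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if lo <= hi:
                total += hi - lo + 1
    # a full-circle pair of wrapping arcs can double-count day boundaries only
    # if both arcs cover the whole year; cap at the year length
    return min(total, YEAR_LENGTH)


def coflowering_matrix(
    intervals: list[FloweringInterval],
) -> tuple[np.ndarray, list[str]]:
    """Proportion of the focal (row) species' flowering days shared with each
    other species.

    Diagonal is 1. Zero-duration focal species cannot occur by construction
    of :class:`FloweringInterval` (a one-day arc has 1 flowering day).
    Returns (matrix, species label order).
    """
    labels = [iv.species_id for iv in intervals]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate species in interval list")
    n = len(intervals)
    mat = np.zeros((n, n))
    for i, focal in enumerate(intervals):
        for j, other in enumerate(intervals):
            if i == j:
                mat[i, j] = 1.0
            else:
                mat[i, j] = interval_overlap_days(focal, other) / focal.flowering_days
    return mat, labels


@dataclass(frozen=True)
class ChangeCell:
    """Signed fold change of a co-flowering proportion, or a GAIN/LOSS/NONE
    marker.

    For proportions p_old, p_new both positive the ratio rho = p_new/p_old is
    reported as rho when overlap increased or stayed equal (rho >= 1) and as
    -rho when it decreased (value in (-1, 0)): 0.2 -> 0.4 gives 2.0 and
    0.4 -> 0.2 gives -0.5.
    """

    kind: ChangeKind
    fold_value: float | None = None


def change_cell(
    p_old: float, p_new: float, decrease_convention: str = "neg_rho"
) -> ChangeCell:
    """Decade-change value for one species pair.

    ``decrease_convention`` selects how a shrinking overlap is signed:
    ``"neg_rho"`` (default) encodes a decrease to a fraction rho < 1 of the
    old value as -rho, matching the doubling/halving examples above;
    ``"neg_inv_rho"`` encodes it as -1/rho, so the magnitude is the fold by
    which overlap shrank (symmetric with the increase side).
    """
    for v in (p_old, p_new):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"proportion {v} outside [0, 1]")
    if decrease_convention not in ("neg_rho", "neg_inv_rho"):
        raise ValueError(f"unknown decrease convention {decrease_convention!r}")
    if p_old == 0.0 and p_new == 0.0:
        return ChangeCell(ChangeKind.NONE)
    if p_old == 0.0:
        return ChangeCell(ChangeKind.GAIN)
    if p_new == 0.0:
        return ChangeCell(ChangeKind.LOSS)
    rho = p_new / p_old
    if rho >= 1.0:
        return ChangeCell(ChangeKind.FOLD, rho)
    return ChangeCell(
        ChangeKind.FOLD, -rho if decrease_convention == "neg_rho" else -1.0 / rho
    )


def change_matrix(
    mat_old: np.ndarray, mat_new: np.ndarray, decrease_convention: str = "neg_rho"
) -> np.ndarray:
    """Element-wise :func:`change_cell` over two co-flowering matrices."""
    if mat_old.shape != mat_new.shape:
        raise ValueError("matrix shapes differ")
    out = np.empty(mat_old.shape, dtype=object)
    for i in range(mat_old.shape[0]):
        for j in range(mat_old.shape[1]):
            out[i, j] = change_cell(
                float(mat_old[i, j]), float(mat_new[i, j]), decrease_convention
            )
    return out


def count_change_categories(change: np.ndarray) -> dict[str, int]:
    """Category counts over the off-diagonal cells of a change matrix.

    ``n_increased`` counts strengthened interactions including outright
    gains; ``n_decreased`` counts weakened ones including outright losses
    ("324 increased, including the gain of 102" style bookkeeping).
    """
    n_inc = n_dec = n_gain = n_loss = n_unchanged = n_none = 0
    n = change.shape[0]
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            cell: ChangeCell = change[i, j]
            if cell.kind is ChangeKind.GAIN:
                n_gain += 1
                n_inc += 1
            elif cell.kind is ChangeKind.LOSS:
                n_loss += 1
                n_dec += 1
            elif cell.kind is ChangeKind.NONE:
                n_none += 1
            elif cell.fold_value > 1.0:
                n_inc += 1
            elif cell.fold_value < 0.0:
                n_dec += 1
            else:  # fold exactly 1
                n_unchanged += 1
    return {
        "n_increased": n_inc,
        "n_decreased": n_dec,
        "n_gain": n_gain,
        "n_loss": n_loss,
        "n_unchanged": n_unchanged,
        "n_none": n_none,
    }


def ternary_reduce(cell: ChangeCell) -> int:
    """Collapse a change cell to +1 (increase), -1 (decrease) or 0."""
    if cell.kind is ChangeKind.GAIN:
        return 1
    if cell.kind is ChangeKind.LOSS:
        return -1
    if cell.kind is ChangeKind.NONE:
        return 0
    if cell.fold_value > 1.0:
        return 1
    if cell.fold_value < 0.0:
        return -1
    return 0


def ternary_matrix(change: np.ndarray) -> np.ndarray:
    out = np.zeros(change.shape, dtype=int)
    for i in range(change.shape[0]):
        for j in range(change.shape[1]):
            if i != j:
                out[i, j] = ternary_reduce(change[i, j])
    return out


def shared_pollinator_mask(
    guilds: list[GuildEntry], labels: list[str]
) -> np.ndarray:
    """Boolean species x species matrix: both entomophilous and their main
    pollinator-agent sets intersect. Wind-pollinated species are excluded
    entirely (all-False rows/columns); the diagonal is False."""
    by_id = {g.species_id: g for g in guilds}
    missing = [l for l in labels if l not in by_id]
    if missing:
        raise KeyError(f"species missing from guild table: {missing}")
    n = len(labels)
    mask = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            ga, gb = by_id[a], by_id[b]
            if ga.wind or gb.wind:
                continue
            mask[i, j] = bool(ga.agents & gb.agents)
    return mask


@dataclass(frozen=True)
class CompetitorSummary:
    """Net ternary co-flowering change restricted to shared-pollinator pairs."""

    per_species: dict[str, int]
    total: int
    mean: float
    sd: float
    excluded_wind: list[str]


def competitor_summary(
    ternary: np.ndarray,
    mask: np.ndarray,
    labels: list[str],
    guilds: list[GuildEntry] | None = None,
) -> CompetitorSummary:
    """Per-species net sum of ternary values over shared-pollinator partners,
    plus the community total and mean +/- sd over included (entomophilous)
    species."""
    if ternary.shape != mask.shape:
        raise ValueError("ternary and mask shapes differ")
    wind_ids: set[str] = set()
    if guilds is not None:
        wind_ids = {g.species_id for g in guilds if g.wind}
    per: dict[str, int] = {}
    for i, lab in enumerate(labels):
        if lab in wind_ids:
            continue
        per[lab] = int(np.sum(ternary[i, :][mask[i, :]]))
    values = np.array(list(per.values()), dtype=float)
    return CompetitorSummary(
        per_species=per,
        total=int(values.sum()) if values.size else 0,
        mean=float(values.mean()) if values.size else float("nan"),
        sd=float(values.std(ddof=1)) if values.size > 1 else float("nan"),
        excluded_wind=sorted(wind_ids & set(labels)),
    )


def rank_order_change(
    phenologies_ref: list[SpeciesDecadePhenology],
    phenologies_new: list[SpeciesDecadePhenology],
) -> pd.DataFrame:
    """Flowering rank order (1 = earliest mean start, anchored at day 1 of
    the year) in each decade and its change.

    Species with an undefined mean start in either decade are excluded with
    a log entry; ties break alphabetically. Returns a DataFrame with columns
    species_id, rank_ref, rank_new, delta_rank (negative = moved earlier in
    the sequence).
    """
    ref = {p.species_id: p.mean_start_doy for p in phenologies_ref}
    new = {p.species_id: p.mean_start_doy for p in phenologies_new}
    shared = sorted(set(ref) & set(new))
    usable = [s for s in shared if np.isfinite(ref[s]) and np.isfinite(new[s])]
    dropped = sorted(set(shared) - set(usable))
    if dropped:
        logger.warning("rank order: dropping species with undefined means: %s", dropped)

    def ranks(startmap):
        order = sorted(usable, key=lambda s: (startmap[s], s))
        return {s: i + 1 for i, s in enumerate(order)}

    r_ref, r_new = ranks(ref), ranks(new)
    return pd.DataFrame(
        {
            "species_id": usable,
            "rank_ref": [r_ref[s] for s in usable],
            "rank_new": [r_new[s] for s in usable],
            "delta_rank": [r_new[s] - r_ref[s] for s in usable],
        }
    )
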