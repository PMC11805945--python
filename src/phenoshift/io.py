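"""Readers and writers for the package's external formats.

Strict, validating I/O with no statistics: weekly flower-count CSVs,
pollinator-guild tables, daily climate CSVs, Newick trees and labelled
numeric matrices. CSV dialect throughout: comma separator, UTF-8, "."
decimal mark, empty field = missing, ISO-8601 dates only.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountRecord",
    "GuildEntry",
    "ClimateDay",
    "ValidationError",
    "GUILD_VOCABULARY",
    "read_counts",
    "write_counts",
    "read_guilds",
    "write_guilds",
    "read_climate",
    "write_climate",
    "read_newick",
    "write_matrix",
    "read_matrix",
]


class ValidationError(ValueError):
    """Structured input-validation failure, naming the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


@dataclass(frozen=True)
class CountRecord:
    """One weekly census of open flowers on one individual plant."""

    species_id: str
    individual_id: str
    census_date: _dt.date
    count: int


@dataclass(frozen=True)
class GuildEntry:
    """Main pollination agents of one species; wind-pollinated species may
    have an empty agent set."""

    species_id: str
    agents: frozenset[str]
    wind: bool


@dataclass(frozen=True)
class ClimateDay:
    """One station-day of climate observations; None marks missing values."""

    station_id: str
    date: _dt.date
    tmin: float | None
    tmean: float | None
    tmax: float | None
    precip: float | None


#: Controlled vocabulary of atomic pollinator-agent tokens. Field phrases
#: such as "small to big bees" are expanded to the atomic size-tagged bee
#: tokens, and "Lepidoptera" to butterflies + sphingids, before matching.
GUILD_VOCABULARY = frozenset(
    {
        "small bees",
        "medium bees",
        "big bees",
        "hoverflies",
        "beeflies",
        "flies",
        "very small flies",
        "butterflies",
        "sphingids",
        "wasps",
        "beetles",
    }
)

_PHRASE_EXPANSIONS = {
    "small to big bees": {"small bees", "medium bees", "big bees"},
    "medium to big bees": {"medium bees", "big bees"},
    "small to medium bees": {"small bees", "medium bees"},
    "lepidoptera": {"butterflies", "sphingids"},
    "bees": {"small bees", "medium bees", "big bees"},
}


def _parse_date(text: str, line: int) -> _dt.date:
    try:
        return _dt.date.fromisoformat(text.strip())
    except ValueError as exc:
        raise ValidationError(f"malformed ISO-8601 date {text!r}", line) from exc


# ---------------------------------------------------------------------------
# flower counts


def read_counts(path) -> list[CountRecord]:
    """Read a long-format weekly flower-count CSV.

    Expected header: ``species_id,individual_id,date,count``. Rejects
    negative counts, malformed dates and duplicate
    (species, individual, date) keys, reporting the 1-based line number.
    """
    records: list[CountRecord] = []
    seen: set[tuple[str, str, _dt.date]] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header[:4] != ["species_id", "individual_id", "date", "count"]:
            raise ValidationError(f"unexpected header {header!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.strip()
            if not raw:
                continue
            parts = raw.split(",")
            if len(parts) != 4:
                raise ValidationError(f"expected 4 fields, got {len(parts)}", lineno)
            sp, ind, date_s, count_s = (p.strip() for p in parts)
            date = _parse_date(date_s, lineno)
            try:
                count = int(count_s)
            except ValueError as exc:
                raise ValidationError(f"non-integer count {count_s!r}", lineno) from exc
            if count < 0:
                raise ValidationError(f"negative count {count}", lineno)
            key = (sp, ind, date)
            if key in seen:
                raise ValidationError(f"duplicate record {key}", lineno)
            seen.add(key)
            records.append(CountRecord(sp, ind, date, count))
    return records


def write_counts(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species_id,individual_id,date,count\n")
        for r in records:
            fh.write(f"{r.species_id},{r.individual_id},{r.census_date.isoformat()},{r.count}\n")


# ---------------------------------------------------------------------------
# pollinator guilds


def tokenize_agents(raw: str) -> set[str]:
    """Split a semicolon-separated agent field into atomic vocabulary tokens.

    Tokens are trimmed, lower-cased and de-duplicated; multi-agent field
    phrases ("small to big bees", "Lepidoptera") expand to their atomic
    tokens. Unknown tokens are kept but logged as warnings — the vocabulary
    is a convention, not a schema.
    """
    out: set[str] = set()
    for piece in raw.split(";"):
        tok = " ".join(piece.strip().lower().split())
        if not tok:
            continue
        if tok in _PHRASE_EXPANSIONS:
            out |= _PHRASE_EXPANSIONS[tok]
        else:
            if tok not in GUILD_VOCABULARY:
                logger.warning("unknown pollinator-agent token %r (kept)", tok)
            out.add(tok)
    return out


def read_guilds(path) -> list[GuildEntry]:
    """Read a pollinator-guild CSV: ``species_id,agents,wind``.

    ``agents`` is semicolon-separated; ``wind`` is true/false. A wind entry
    with an empty agent set is valid. Duplicate species are an error.
    """
    entries: list[GuildEntry] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header[:1] != ["species_id"]:
            raise ValidationError(f"unexpected header {header!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw.strip():
                continue
            parts = raw.split(",")
            if len(parts) != 3:
                raise ValidationError(f"expected 3 fields, got {len(parts)}", lineno)
            sp, agents_s, wind_s = parts[0].strip(), parts[1], parts[2].strip().lower()
            if sp in seen:
                raise ValidationError(f"duplicated species_id {sp!r}", lineno)
            seen.add(sp)
            if wind_s not in {"true", "false"}:
                raise ValidationError(f"wind must be true/false, got {wind_s!r}", lineno)
            entries.append(
                GuildEntry(sp, frozenset(tokenize_agents(agents_s)), wind_s == "true")
            )
    return entries


def write_guilds(entries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species_id,agents,wind\n")
        for e in entries:
            fh.write(f"{e.species_id},{';'.join(sorted(e.agents))},{str(e.wind).lower()}\n")


# ---------------------------------------------------------------------------
# climate


def _parse_opt_float(text: str, what: str, line: int) -> float | None:
    text = text.strip()
    if text == "":
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(f"non-numeric {what} {text!r}", line) from exc


def read_climate(path) -> list[ClimateDay]:
    """Read a daily climate CSV: ``station_id,date,tmin,tmean,tmax,precip``.

    Empty fields are missing. Enforces tmin <= tmean <= tmax (when all
    present) and precip >= 0.
    """
    days: list[ClimateDay] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip().split(",")
        if header[:6] != ["station_id", "date", "tmin", "tmean", "tmax", "precip"]:
            raise ValidationError(f"unexpected header {header!r}", 1)
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split(",")
            if len(parts) != 6:
                raise ValidationError(f"expected 6 fields, got {len(parts)}", lineno)
            station = parts[0].strip()
            date = _parse_date(parts[1], lineno)
            tmin = _parse_opt_float(parts[2], "tmin", lineno)
            tmean = _parse_opt_float(parts[3], "tmean", lineno)
            tmax = _parse_opt_float(parts[4], "tmax", lineno)
            precip = _parse_opt_float(parts[5], "precip", lineno)
            if tmin is not None and tmean is not None and tmax is not None:
                if not (tmin <= tmean <= tmax):
                    raise ValidationError(
                        f"temperature ordering violated: {tmin} <= {tmean} <= {tmax}", lineno
                    )
            if precip is not None and precip < 0:
                raise ValidationError(f"negative precipitation {precip}", lineno)
            days.append(ClimateDay(station, date, tmin, tmean, tmax, precip))
    return days


def write_climate(days, path) -> None:
    def fmt(v):
        return "" if v is None else f"{v:.3f}"

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("station_id,date,tmin,tmean,tmax,precip\n")
        for d in days:
            fh.write(
                f"{d.station_id},{d.date.isoformat()},{fmt(d.tmin)},{fmt(d.tmean)},"
                f"{fmt(d.tmax)},{fmt(d.precip)}\n"
            )


# ---------------------------------------------------------------------------
# trees and matrices


def read_newick(path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Tip labels must be unique; negative branch lengths are rejected. Whether
    the tree is ultrametric is checked and reported via logging, not
    enforced.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"unreadable Newick file: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValidationError(f"negative branch length {edge.length}")
    depths = []
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    if depths and (max(depths) - min(depths)) > 1e-6 * max(max(depths), 1.0):
        logger.info("tree is not ultrametric (tip depth range %.6g..%.6g)",
                    min(depths), max(depths))
    return tree


def write_matrix(matrix, labels, path) -> None:
    """Write a labelled square matrix as CSV with 12-decimal fixed format.

    Cells may be numbers or sentinel strings (e.g. "gain"/"loss" in change
    matrices); numeric cells round-trip exactly at 12 decimals.
    """
    matrix = np.asarray(matrix, dtype=object)
    n = len(labels)
    if matrix.shape != (n, n):
        raise ValidationError(f"matrix shape {matrix.shape} != ({n}, {n})")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("," + ",".join(labels) + "\n")
        for i, lab in enumerate(labels):
            cells = []
            for v in matrix[i]:
                if isinstance(v, str):
                    cells.append(v)
                elif v is None or (isinstance(v, float) and math.isnan(v)):
                    cells.append("")
                else:
                    cells.append(f"{float(v):.12f}")
            fh.write(lab + "," + ",".join(cells) + "\n")


def read_matrix(path) -> tuple[np.ndarray, list[str]]:
    """Read a labelled matrix written by :func:`write_matrix`.

    Returns an object-dtype array (floats, sentinel strings, or nan for
    empty cells) and the label list.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    labels = list(df.index)
    if labels != list(df.columns):
        raise ValidationError("row and column labels differ")
    out = np.empty(df.shape, dtype=object)
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = df.iat[i, j]
            if cell == "":
                out[i, j] = float("nan")
            else:
                try:
                    out[i, j] = float(cell)
                except ValueError:
                    out[i, j] = cell
    return out, labels
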