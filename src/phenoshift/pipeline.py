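"""End-to-end orchestration: from inputs (real files or a simulation spec)
to the full set of report tables.

``run`` produces, under one output directory: the per-species decade shift
table, the shift-pattern counts, the community flowering curves with the
community peak-shift test, the per-decade co-flowering matrices with the
change matrix and its category counts, the shared-pollinator competitor
summary, the flowering rank-order table, the climate trend table, and the
phylogenetic-signal fits — plus a JSON manifest recording configuration and
seed. Stages whose inputs are absent are skipped and recorded as such; the
pipeline is deterministic given (config, seed), with every stochastic step
drawing from a named substream of the master seed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import climate as climate_mod
from . import coflowering as cofl
from . import io as io_mod
from . import phenometrics as phen
from . import phylo as phylo_mod
from . import simulate as sim

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run", "phenologies_from_records", "decade_of_year"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    Exactly one of ``simulation`` (a CommunitySpec; inputs are generated) or
    the explicit input paths may be active. ``decade1_years`` /
    ``decade2_years`` assign censuses to observation windows when reading
    real files; with a simulation they come from the spec.
    """

    output_dir: str | Path = "run_output"
    simulation: sim.CommunitySpec | None = None
    counts_path: str | None = None
    guilds_path: str | None = None
    climate_path: str | None = None
    tree_path: str | None = None
    decade1_years: tuple[int, ...] = (1985, 1986, 1987)
    decade2_years: tuple[int, ...] = (2020, 2021, 2022)
    alpha: float = 0.05
    n_perm: int = 1999
    seed: int = 0
    log_start_shift_trait: bool = True

    def __post_init__(self):
        if self.simulation is not None and self.counts_path is not None:
            raise ValueError("exactly one of simulation or real inputs must be active")


def decade_of_year(year: int, d1: tuple[int, ...], d2: tuple[int, ...]) -> str | None:
    if year in d1:
        return "d1"
    if year in d2:
        return "d2"
    return None


def phenologies_from_records(
    records: list[io_mod.CountRecord],
    decade1_years: tuple[int, ...],
    decade2_years: tuple[int, ...],
) -> dict[str, dict[str, list[phen.IndividualPhenology]]]:
    """Group census records into per-decade, per-species individual
    phenologies.

    A record belongs to the decade containing its census year; each
    (species, individual, decade) series yields at most one phenology (its
    longest flowering season). Returns {"d1": {species: [...]}, "d2": ...}.
    """
    grouped: dict[tuple[str, str, str], list[io_mod.CountRecord]] = {}
    for r in records:
        dec = decade_of_year(r.census_date.year, decade1_years, decade2_years)
        if dec is None:
            continue
        grouped.setdefault((dec, r.species_id, r.individual_id), []).append(r)
    out: dict[str, dict[str, list[phen.IndividualPhenology]]] = {"d1": {}, "d2": {}}
    for (dec, sp, ind), recs in sorted(grouped.items()):
        p = phen.extract_individual_phenology(
            sp, ind, [r.census_date for r in recs], [r.count for r in recs]
        )
        if p is not None:
            out[dec].setdefault(sp, []).append(p)
    return out


def _named_seed(master_seed: int, index: int) -> int:
    """Reproducible substream seed below 2**31 for pipeline stage ``index``."""
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31)
    )


def run(config: RunConfig) -> dict:
    """Execute the full analysis; returns a manifest dict (also written to
    ``manifest.json`` in the output directory)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "alpha": config.alpha,
        "timestamp": _dt.datetime.now().isoformat(timespec="seconds"),
        "skipped": [],
        "artifacts": {},
    }

    # ------------------------------------------------------------------ inputs
    guilds = None
    tree = None
    climate_days = None
    if config.simulation is not None:
        spec = config.simulation
        d1_years, d2_years = spec.decade1_years, spec.decade2_years
        records, truth = sim.generate_counts(spec, _named_seed(config.seed, 1))
        truth.to_csv(outdir / "truth.csv", index=False)
        guilds = sim.generate_guilds(spec)
        climate_days = sim.generate_climate(spec.climate, _named_seed(config.seed, 2))
        tree = sim.generate_tree(
            [s.species_id for s in spec.species], _named_seed(config.seed, 3)
        )
        manifest["mode"] = "simulation"
        manifest["n_species"] = len(spec.species)
    else:
        d1_years, d2_years = config.decade1_years, config.decade2_years
        if config.counts_path is None:
            raise ValueError("neither simulation spec nor counts path given")
        records = io_mod.read_counts(config.counts_path)
        if config.guilds_path:
            guilds = io_mod.read_guilds(config.guilds_path)
        if config.climate_path:
            climate_days = io_mod.read_climate(config.climate_path)
        if config.tree_path:
            tree = io_mod.read_newick(config.tree_path)
        manifest["mode"] = "files"

    # -------------------------------------------------- per-species phenology
    phenologies = phenologies_from_records(records, d1_years, d2_years)
    species_both = sorted(set(phenologies["d1"]) & set(phenologies["d2"]))
    pooled = {
        dec: {
            sp: phen.pool_species_decade(phenologies[dec][sp], dec)
            for sp in phenologies[dec]
        }
        for dec in ("d1", "d2")
    }

    comparisons: list[phen.ShiftComparison] = []
    for i, sp in enumerate(species_both):
        comparisons.append(
            phen.compare_decades(
                sp,
                phenologies["d1"][sp],
                phenologies["d2"][sp],
                alpha=config.alpha,
                n_perm=config.n_perm,
                seed=_named_seed(config.seed, 100 + i),
            )
        )

    shift_rows = []
    for c in comparisons:
        row = {"species_id": c.species_id, "pattern": c.pattern.value}
        for name in ("start", "end", "peak", "duration"):
            s: phen.ParameterShift = getattr(c, name)
            row[f"{name}_delta_days"] = s.delta_days
            row[f"{name}_p"] = s.p_value
            row[f"{name}_significant"] = s.significant
        shift_rows.append(row)
    shift_table = pd.DataFrame(shift_rows)
    # positive delta = advance for dates, lengthening for duration
    shift_table.to_csv(outdir / "species_shift_table.csv", index=False)
    manifest["artifacts"]["species_shift_table"] = "species_shift_table.csv"

    pattern_counts = (
        shift_table["pattern"].value_counts().rename_axis("pattern").reset_index(name="n")
        if len(shift_table)
        else pd.DataFrame(columns=["pattern", "n"])
    )
    if len(pattern_counts):
        pattern_counts["percent"] = 100.0 * pattern_counts["n"] / pattern_counts["n"].sum()
    pattern_counts.to_csv(outdir / "pattern_counts.csv", index=False)
    manifest["artifacts"]["pattern_counts"] = "pattern_counts.csv"

    # ------------------------------------------------------- community curves
    curves = {}
    for dec in ("d1", "d2"):
        curve = phen.build_community_curve(list(pooled[dec].values()), dec)
        curves[dec] = curve
    curve_df = pd.DataFrame(
        {
            "doy": np.arange(1, 366),
            "n_species_d1": curves["d1"].counts,
            "n_species_d2": curves["d2"].counts,
        }
    )
    curve_df.to_csv(outdir / "community_curves.csv", index=False)
    manifest["artifacts"]["community_curves"] = "community_curves.csv"

    # community mean-date contrast on the per-day species counts (the curve)
    if len(species_both) >= 2:
        doys = np.arange(1, 366)
        shift, test, s1, s2 = phen.community_mean_peak_shift(
            doys, doys, curves["d1"].counts, curves["d2"].counts
        )
        manifest["community_peak_shift_days"] = shift
        manifest["community_peak_shift_p"] = test.p_value
        manifest["community_peak_input"] = test.note
        manifest["community_r_d1"] = s1.r
        manifest["community_r_d2"] = s2.r
    else:
        manifest["skipped"].append("community_peak_shift")

    # ------------------------------------------------------------ co-flowering
    intervals = {
        dec: [
            cofl.interval_from_phenology(pooled[dec][sp])
            for sp in species_both
            if np.isfinite(pooled[dec][sp].mean_start_doy)
        ]
        for dec in ("d1", "d2")
    }
    common = sorted(
        {iv.species_id for iv in intervals["d1"]} & {iv.species_id for iv in intervals["d2"]}
    )
    mats = {}
    for dec in ("d1", "d2"):
        ivs = sorted(
            (iv for iv in intervals[dec] if iv.species_id in common),
            key=lambda iv: iv.species_id,
        )
        mat, labels = cofl.coflowering_matrix(ivs)
        mats[dec] = mat
        io_mod.write_matrix(mat, labels, outdir / f"coflowering_{dec}.csv")
        manifest["artifacts"][f"coflowering_{dec}"] = f"coflowering_{dec}.csv"
    change = cofl.change_matrix(mats["d1"], mats["d2"])
    rendered = np.empty(change.shape, dtype=object)
    for i in range(change.shape[0]):
        for j in range(change.shape[1]):
            cell: cofl.ChangeCell = change[i, j]
            rendered[i, j] = (
                cell.fold_value if cell.kind is cofl.ChangeKind.FOLD else cell.kind.value
            )
    io_mod.write_matrix(rendered, common, outdir / "coflowering_change.csv")
    manifest["artifacts"]["coflowering_change"] = "coflowering_change.csv"
    manifest["change_categories"] = cofl.count_change_categories(change)

    # ------------------------------------------- shared-pollinator competitors
    if guilds is not None:
        ternary = cofl.ternary_matrix(change)
        mask = cofl.shared_pollinator_mask(guilds, common)
        summary = cofl.competitor_summary(ternary, mask, common, guilds)
        pd.DataFrame(
            {
                "species_id": list(summary.per_species),
                "net_change": list(summary.per_species.values()),
                "n_partners": [int(mask[common.index(s)].sum()) for s in summary.per_species],
            }
        ).to_csv(outdir / "competitor_summary.csv", index=False)
        manifest["artifacts"]["competitor_summary"] = "competitor_summary.csv"
        manifest["competitor_total"] = summary.total
        manifest["competitor_mean"] = summary.mean
        manifest["competitor_sd"] = summary.sd
        manifest["competitor_excluded_wind"] = summary.excluded_wind
    else:
        manifest["skipped"].append("competitor_summary")

    # --------------------------------------------------------------- rank order
    ranks = cofl.rank_order_change(
        [pooled["d1"][sp] for sp in species_both],
        [pooled["d2"][sp] for sp in species_both],
    )
    ranks.to_csv(outdir / "rank_order.csv", index=False)
    manifest["artifacts"]["rank_order"] = "rank_order.csv"

    # ------------------------------------------------------------------ climate
    if climate_days is not None:
        daily = climate_mod.average_stations(climate_days)
        trends = climate_mod.trend_table(daily)
        trends.to_csv(outdir / "climate_trends.csv", index=False)
        manifest["artifacts"]["climate_trends"] = "climate_trends.csv"
    else:
        manifest["skipped"].append("climate_trends")

    # --------------------------------------------------------- duration ~ shift
    if len(shift_table) >= 3:
        try:
            fit = climate_mod.duration_vs_shift_regression(
                shift_table["start_delta_days"], shift_table["duration_delta_days"]
            )
            manifest["duration_vs_shift"] = dataclasses.asdict(fit)
        except ValueError as exc:
            logger.warning("duration~shift regression skipped: %s", exc)
            manifest["skipped"].append("duration_vs_shift")
    else:
        manifest["skipped"].append("duration_vs_shift")

    # ---------------------------------------------------------- phylo signal
    if tree is not None and len(shift_table) >= 4:
        fits = {}
        for trait_name, col in (
            ("start_shift", "start_delta_days"),
            ("duration_change", "duration_delta_days"),
        ):
            values = dict(zip(shift_table["species_id"], shift_table[col]))
            values = {k: v for k, v in values.items() if np.isfinite(v)}
            if config.log_start_shift_trait:
                values = phylo_mod.log_shift_transform(values)
            tips = {l.taxon.label for l in tree.leaf_node_iter()}
            pruned = tree.extract_tree_with_taxa_labels(sorted(tips & set(values)))
            try:
                fit = phylo_mod.fit_lambda(values, pruned)
            except (ValueError, KeyError) as exc:
                logger.warning("lambda fit for %s skipped: %s", trait_name, exc)
                continue
            fits[trait_name] = {
                "lambda_hat": fit.lambda_hat,
                "sigma2_hat": fit.sigma2_hat,
                "logL": fit.logL,
                "logL_at_lambda0": fit.logL_at_lambda0,
                "p_lrt": fit.p_lrt,
                "n_tips": fit.n_tips,
            }
        with open(outdir / "lambda_fits.json", "w", encoding="utf-8") as fh:
            json.dump(fits, fh, indent=2)
        manifest["artifacts"]["lambda_fits"] = "lambda_fits.json"
    else:
        manifest["skipped"].append("lambda_fits")

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
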