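"""End-to-end orchestration: tables in, EAF/growth/flux tables out.

``qsip_analysis`` is the in-memory pipeline (DataFrames in, DataFrames
out); ``run_qsip`` / ``run_flux`` wrap it with config parsing and TSV/JSON
output for the command line.  All randomness flows from the single run
seed; reruns with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import data_model as dm
from .flux import ChamberConfig, FluxSeries, compute_flux, flux_table
from .growth import (EnrichmentModel, cumulative_growth, family_warming_response,
                     mixed_water_enrichment, phylum_contributions,
                     relative_growth_rate)
from .qsip import FilterCriteria, bootstrap_eaf, filter_taxa, taxon_tube_wads

logger = logging.getLogger("qsipgrowth")

EXIT_CONFIG_ERROR = 2
EXIT_VALIDATION_ERROR = 3
EXIT_COMPUTATION_ERROR = 4


@dataclass
class RunConfig:
    """Parsed run configuration (paths, filter, bootstrap, models)."""

    inputs: dict[str, str] = field(default_factory=dict)
    outdir: str = "qsip_out"
    n_boot: int = 1000
    seed: int = 1
    filter_criteria: FilterCriteria = field(default_factory=FilterCriteria)
    enrichment: EnrichmentModel = field(default_factory=EnrichmentModel)
    chamber: dict[str, Any] = field(default_factory=dict)
    collar_heights: dict[str, float] = field(default_factory=dict)
    header_mapping: dict[str, dict[str, str]] = field(default_factory=dict)
    log_level: str = "INFO"


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    boot = raw.get("bootstrap", {})
    cfg = RunConfig(
        inputs=raw.get("inputs", {}),
        outdir=raw.get("outdir", "qsip_out"),
        n_boot=int(boot.get("n_boot", 1000)),
        seed=int(boot.get("seed", 1)),
        filter_criteria=FilterCriteria(**raw.get("filter", {})),
        enrichment=EnrichmentModel(**raw.get("enrichment", {})),
        chamber=raw.get("chamber", {}),
        collar_heights={str(k): float(v)
                        for k, v in raw.get("collar_heights", {}).items()},
        header_mapping=raw.get("header_mapping", {}),
        log_level=raw.get("log_level", "INFO"),
    )
    for name, p in cfg.inputs.items():
        if not Path(p).exists():
            raise FileNotFoundError(f"input '{name}' not found: {p}")
    return cfg


# ---------------------------------------------------------------------------
# qSIP pipeline
# ---------------------------------------------------------------------------

def qsip_analysis(fractions: pd.DataFrame, features: pd.DataFrame,
                  tubes: pd.DataFrame, water: pd.DataFrame,
                  taxonomy: pd.DataFrame | None = None,
                  criteria: FilterCriteria = FilterCriteria(),
                  enrichment_model: EnrichmentModel = EnrichmentModel(),
                  n_boot: int = 1000, seed: int = 1) -> dict[str, Any]:
    """Full qSIP chain on in-memory tables.

    Returns a dict with DataFrames ``eaf`` (per taxon and group, with
    bootstrap CI and significance), ``growth`` (RGR and copy-weighted
    growth), ``cumulative`` (per group), ``phylum`` (proportions per
    group), ``family_warming`` (per site), ``dropped`` (taxa excluded with
    reasons) and the run ``manifest`` dict.
    """
    dm.validate_fractions(fractions)
    dm.validate_features(features)
    dm.validate_tubes(tubes)
    dm.validate_water(water)

    fractions = dm.flag_density_window(fractions)
    tube_meta = tubes.set_index("tube_id")
    groups = sorted(map(tuple, tubes[["site", "temperature_treatment"]]
                        .drop_duplicates().to_numpy()))

    # presence filter and per-(taxon, tube) WAD profiles
    passed = filter_taxa(features, tubes, criteria, fractions)
    wads = taxon_tube_wads(features, fractions)
    wads = wads.merge(tube_meta[["site", "temperature_treatment",
                                 "isotope_treatment"]],
                      left_on="tube_id", right_index=True)

    # per-tube soil-water enrichment, averaged within group over heavy tubes
    water_by_tube = water.set_index("tube_id")
    enr_by_group: dict[tuple[str, str], float] = {}
    for grp in groups:
        heavy_ids = tubes.loc[
            (tubes["site"] == grp[0])
            & (tubes["temperature_treatment"] == grp[1])
            & (tubes["isotope_treatment"] == "heavy"), "tube_id"]
        vals = [mixed_water_enrichment(
                    water_by_tube.loc[t, "initial_water_mass"],
                    water_by_tube.loc[t, "added_water_mass"],
                    natural_af=enrichment_model.natural_atom_fraction,
                    tracer_af=water_by_tube.loc[t, "added_atom_fraction"])
                for t in heavy_ids if t in water_by_tube.index]
        if not vals:
            raise ValueError(f"group {grp}: no water-addition record for any "
                             "heavy tube")
        enr_by_group[grp] = float(np.mean(vals))

    # total reads and gene copies per tube (for group-level taxon abundances)
    tube_reads = features.groupby("tube_id")["read_count"].sum()
    in_win = fractions[fractions["in_window"]]
    tube_copies = in_win.groupby("tube_id")["gene_copies"].sum()

    root = np.random.SeedSequence(seed)
    eaf_rows, dropped_rows = [], []
    rgr_draws: dict[tuple[str, str], dict[str, np.ndarray]] = {g: {} for g in groups}

    group_taxa_counts: dict[tuple[str, str], dict[str, int]] = {}
    for grp in groups:
        site, treat = grp
        gtubes = tube_meta[(tube_meta["site"] == site)
                           & (tube_meta["temperature_treatment"] == treat)]
        present = set(features.loc[features["tube_id"].isin(gtubes.index),
                                   "taxon_id"])
        n_sig = 0
        gw = wads[(wads["site"] == site) & (wads["temperature_treatment"] == treat)]
        denom = (enr_by_group[grp] * enrichment_model.oxygen_from_water_fraction
                 * enrichment_model.incubation_days)
        for taxon in sorted(passed[grp]):
            tw = gw[gw["taxon_id"] == taxon]
            light = tw.loc[tw["isotope_treatment"] == "light", "wad"].to_numpy()
            heavy = tw.loc[tw["isotope_treatment"] == "heavy", "wad"].to_numpy()
            child = root.spawn(1)[0]
            if len(light) == 0 or len(heavy) == 0:
                dropped_rows.append({
                    "taxon_id": taxon, "site": site,
                    "temperature_treatment": treat,
                    "reason": "no defined WAD in one isotope treatment"})
                continue
            est = bootstrap_eaf(taxon, site, treat, light, heavy,
                                n_boot=n_boot, seed=np.random.default_rng(child))
            n_sig += int(est.significant)
            eaf_rows.append({
                "taxon_id": taxon, "site": site, "temperature_treatment": treat,
                "eaf_median": est.eaf_median, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "n_boot": n_boot,
                "n_light": est.n_light, "n_heavy": est.n_heavy,
                "significant": est.significant})
            rgr_draws[grp][taxon] = est.draws / denom
        for taxon in sorted(present - passed[grp]):
            dropped_rows.append({
                "taxon_id": taxon, "site": site, "temperature_treatment": treat,
                "reason": (f"present in <{criteria.min_fractions} fractions of "
                           f"<{criteria.min_replicates} replicates of an "
                           "isotope treatment")})
        group_taxa_counts[grp] = {
            "total_asvs": len(present),
            "asvs_with_growth_rate": len(rgr_draws[grp]),
            "asvs_significant": n_sig,
        }

    eaf = pd.DataFrame(eaf_rows, columns=[
        "taxon_id", "site", "temperature_treatment", "eaf_median", "ci_low",
        "ci_high", "n_boot", "n_light", "n_heavy", "significant"])

    # growth table: RGR x group-mean gene copies per taxon
    growth_rows = []
    for grp in groups:
        site, treat = grp
        gtube_ids = tube_meta[(tube_meta["site"] == site)
                              & (tube_meta["temperature_treatment"] == treat)].index
        sub = eaf[(eaf["site"] == site) & (eaf["temperature_treatment"] == treat)]
        gfeat = features[features["tube_id"].isin(gtube_ids)]
        taxon_tube_reads = gfeat.groupby(["taxon_id", "tube_id"])["read_count"].sum()
        for _, row in sub.iterrows():
            taxon = row["taxon_id"]
            # per-tube relative abundance x per-tube total copies, group mean
            per_tube = []
            for t in gtube_ids:
                reads = taxon_tube_reads.get((taxon, t), 0)
                total = tube_reads.get(t, 0)
                copies = tube_copies.get(t, 0.0)
                per_tube.append(0.0 if total == 0 else reads / total * copies)
            gene_copies = float(np.mean(per_tube))
            rgr = relative_growth_rate(
                row["eaf_median"], enr_by_group[grp],
                enrichment_model.oxygen_from_water_fraction,
                enrichment_model.incubation_days)
            growth_rows.append({
                "taxon_id": taxon, "site": site, "temperature_treatment": treat,
                "eaf_median": row["eaf_median"], "rgr": rgr,
                "gene_copies": gene_copies, "growth": rgr * gene_copies})
    growth = pd.DataFrame(growth_rows, columns=[
        "taxon_id", "site", "temperature_treatment", "eaf_median", "rgr",
        "gene_copies", "growth"])
    if taxonomy is not None and len(growth):
        growth = growth.merge(
            taxonomy[["taxon_id", "phylum", "family"]], on="taxon_id", how="left")

    cumulative_rows, phylum_rows = [], []
    for grp in groups:
        site, treat = grp
        sub = growth[(growth["site"] == site)
                     & (growth["temperature_treatment"] == treat)]
        if not len(sub):
            continue
        cumulative_rows.append({
            "site": site, "temperature_treatment": treat,
            "cumulative_growth": cumulative_growth(sub),
            "n_taxa": len(sub)})
        try:
            props = phylum_contributions(sub)
        except ValueError:
            logger.warning("group %s: total growth not positive, phylum "
                           "proportions undefined", grp)
            continue
        for phylum in sorted(props):
            phylum_rows.append({"site": site, "temperature_treatment": treat,
                                "phylum": phylum, "proportion": props[phylum]})
    cumulative = pd.DataFrame(cumulative_rows, columns=[
        "site", "temperature_treatment", "cumulative_growth", "n_taxa"])
    phylum = pd.DataFrame(phylum_rows, columns=[
        "site", "temperature_treatment", "phylum", "proportion"])

    # family-level warming response per site
    fam_rows = []
    if taxonomy is not None:
        asv_family = dict(zip(taxonomy["taxon_id"], taxonomy["family"]))
        for site in sorted({g[0] for g in groups}):
            ctl, wrm = (site, "control"), (site, "warmed")
            if ctl not in rgr_draws or wrm not in rgr_draws:
                continue
            for test in family_warming_response(
                    rgr_draws[ctl], rgr_draws[wrm], asv_family, site):
                fam_rows.append({
                    "family": test.family, "site": site,
                    "diff_median": test.diff_median, "ci_low": test.ci_low,
                    "ci_high": test.ci_high, "n_boot": test.n_boot,
                    "increased_with_warming": test.increased_with_warming})
    family_warming = pd.DataFrame(fam_rows, columns=[
        "family", "site", "diff_median", "ci_low", "ci_high", "n_boot",
        "increased_with_warming"])

    manifest = {
        "package_version": __version__,
        "seed": seed, "n_boot": n_boot,
        "sign_convention": "family diff = warmed - control; positive = "
                           "growth increased with warming",
        "filter": asdict(criteria),
        "enrichment": asdict(enrichment_model),
        "soil_water_enrichment_by_group": {
            f"{s}/{t}": enr_by_group[(s, t)] for s, t in groups},
        "groups": {f"{s}/{t}": group_taxa_counts[(s, t)] for s, t in groups},
    }
    return {"eaf": eaf, "growth": growth, "cumulative": cumulative,
            "phylum": phylum, "family_warming": family_warming,
            "dropped": pd.DataFrame(
                dropped_rows, columns=["taxon_id", "site",
                                       "temperature_treatment", "reason"]),
            "manifest": manifest, "rgr_draws": rgr_draws}


def run_qsip(config: RunConfig) -> dict[str, Any]:
    """Read inputs per config, run the qSIP chain, write the result bundle."""
    hm = config.header_mapping
    fractions = dm.read_fraction_table(config.inputs["fractions"],
                                       hm.get("fractions"))
    tubes = dm.read_tube_table(config.inputs["tubes"], hm.get("tubes"))
    features = dm.read_feature_table(config.inputs["features"], tubes,
                                     hm.get("features"))
    water = dm.read_water_table(config.inputs["water"], hm.get("water"))
    taxonomy = (dm.read_taxonomy_table(config.inputs["taxonomy"],
                                       hm.get("taxonomy"))
                if "taxonomy" in config.inputs else None)

    result = qsip_analysis(fractions, features, tubes, water, taxonomy,
                           criteria=config.filter_criteria,
                           enrichment_model=config.enrichment,
                           n_boot=config.n_boot, seed=config.seed)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dm.write_table(result["eaf"], outdir / "eaf.tsv")
    dm.write_table(result["growth"], outdir / "growth.tsv")
    dm.write_table(result["cumulative"], outdir / "cumulative_growth.tsv")
    dm.write_table(result["phylum"], outdir / "phylum_contributions.tsv")
    dm.write_table(result["family_warming"], outdir / "family_warming.tsv")
    dm.write_table(result["dropped"], outdir / "dropped_taxa.tsv")
    (outdir / "manifest.json").write_text(
        json.dumps(result["manifest"], indent=2, sort_keys=True) + "\n")
    n_passed = sum(g["asvs_with_growth_rate"]
                   for g in result["manifest"]["groups"].values())
    logger.info("qSIP run complete: %d taxa passed filter across groups; "
                "outputs in %s", n_passed, outdir)
    return result


# ---------------------------------------------------------------------------
# flux pipeline
# ---------------------------------------------------------------------------

def read_flux_series(path: str | Path) -> list[tuple[FluxSeries, dict]]:
    """Read a long CSV/TSV of chamber closures.

    Required columns: plot_id, day_index, mode, time_s, co2, h2o.  Optional
    per-closure overrides: temperature_k, pressure_kpa.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    required = ["plot_id", "day_index", "mode", "time_s", "co2", "h2o"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise dm.ParseError(f"{path}: missing flux column(s) {missing}")
    out = []
    for (plot, day, mode), g in df.groupby(["plot_id", "day_index", "mode"]):
        g = g.sort_values("time_s")
        series = FluxSeries(timestamps=g["time_s"].to_numpy(),
                            co2=g["co2"].to_numpy(), h2o=g["h2o"].to_numpy(),
                            mode=str(mode), plot_id=str(plot),
                            day_index=int(day))
        overrides = {}
        if "temperature_k" in g.columns:
            overrides["temperature"] = float(g["temperature_k"].iloc[0])
        if "pressure_kpa" in g.columns:
            overrides["pressure"] = float(g["pressure_kpa"].iloc[0])
        out.append((series, overrides))
    return out


def run_flux(config: RunConfig) -> pd.DataFrame:
    """Compute ER/NEE/GEP per plot-day from a flux time-series file."""
    base = dict(config.chamber)
    results = []
    for series, overrides in read_flux_series(config.inputs["flux_series"]):
        params = {**base, **overrides}
        if series.plot_id in config.collar_heights:
            params["collar_height"] = config.collar_heights[series.plot_id]
        results.append(compute_flux(series, ChamberConfig(**params)))
    table = flux_table(results)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dm.write_table(table, outdir / "flux_results.tsv")
    logger.info("flux run complete: %d plot-day rows; outputs in %s",
                len(table), outdir)
    return table
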