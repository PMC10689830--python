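"""Synthetic density-gradient qSIP datasets and chamber series with known truth.

The generator emulates the field tracer design: per (site, temperature)
group, five replicate plots each contribute one light (natural-abundance
water) and one heavy (98 atom % 18O water) tube; each tube yields ~23
density fractions spanning 1.65-1.74 g/ml.  For every taxon the light-tube
target WAD follows from its GC content through the GC-density calibration,
and the heavy-tube target WAD is obtained by inverting the exact estimator
chain at the taxon's true EAF — so at zero noise the pipeline recovers
truth exactly and estimator bugs surface as recovery failures.  Taxon DNA
is spread over the fraction grid with a Gaussian density kernel (midpoint
mass assignment), reads are drawn multinomially at a fixed per-fraction
depth, and qPCR totals are the per-fraction copy sums under multiplicative
lognormal noise.  Between-tube variability enters as an independent
Gaussian jitter on each taxon's target WAD per tube.

Randomness derives from a single root seed fanned out with
``numpy.random.SeedSequence.spawn``: one child stream per tube, in the
deterministic order tubes are generated.

Not simulated: sequencing error, chimeras, or compositional artifacts of
amplicon workflows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import qsip
from .flux import ChamberConfig, FluxSeries, flux_from_slope
from .growth import (EnrichmentModel, mixed_water_enrichment,
                     relative_growth_rate)

logger = logging.getLogger("qsipgrowth")

MAX_TRUE_EAF: float = 1.0 - qsip.NATURAL_18O_ABUNDANCE

_PHYLA = ("Proteobacteria", "Acidobacteriota", "Bacteroidota",
          "Actinobacteriota", "Cyanobacteria", "Verrucomicrobiota")
_FAMILIES_PER_PHYLUM = 2


@dataclass(frozen=True)
class SimTaxonSpec:
    """Ground truth for one simulated ASV."""

    taxon_id: str
    gc: float                    # GC content fraction
    true_eaf: float              # 18O excess atom fraction actually incorporated
    relative_abundance: float    # fraction of community copies
    density_dispersion: float = 0.004   # g/ml spread of the taxon's DNA
    phylum: str = "Proteobacteria"
    family: str = "SimFamily1"

    def __post_init__(self) -> None:
        if not 0 <= self.true_eaf <= MAX_TRUE_EAF:
            raise ValueError(f"true_eaf must be in [0, {MAX_TRUE_EAF:.6f}]")
        if self.density_dispersion <= 0:
            raise ValueError("density_dispersion must be positive")

    @property
    def light_wad(self) -> float:
        """Target light-tube WAD implied by GC content."""
        return qsip.GC_DENSITY_INTERCEPT + qsip.GC_DENSITY_SLOPE * self.gc

    @property
    def heavy_wad(self) -> float:
        """Target heavy-tube WAD: exact inverse of the EAF estimator chain."""
        m_light = qsip.MW_GC_SLOPE * self.gc + qsip.MW_INTERCEPT
        m_lab = m_light + (self.true_eaf / (1.0 - qsip.NATURAL_18O_ABUNDANCE)
                           * qsip.MW_FULL_18O_SHIFT)
        return self.light_wad * m_lab / m_light


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters of the gradient simulator."""

    n_replicate_plots: int = 5
    n_fractions: int = 23
    density_min: float = 1.65        # g/ml, lightest fraction
    density_max: float = 1.74        # g/ml, heaviest fraction
    read_depth: int = 10_000         # reads per sequenced fraction
    qpcr_total: float = 2.5e9        # 16S copies per g dry mass per tube
    qpcr_log_sd: float = 0.1         # lognormal sigma on per-fraction totals
    tube_wad_jitter: float = 0.002   # g/ml sd of per-tube, per-taxon WAD shift
    initial_water_mass: float = 5.0  # g of ambient water in the core
    added_water_mass: float = 5.0    # g of water added (doubles water content)
    tracer_atom_fraction: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fractions < 2 or self.n_replicate_plots < 1:
            raise ValueError("need >= 2 fractions and >= 1 replicate plot")
        if self.density_max <= self.density_min:
            raise ValueError("density grid must be increasing")

    @property
    def density_grid(self) -> np.ndarray:
        """Fraction densities, index 1 = heaviest (descending)."""
        return np.linspace(self.density_max, self.density_min, self.n_fractions)


def default_taxa(n: int, rng: np.random.Generator,
                 eaf_low: float = 0.0, eaf_high: float = 0.5,
                 true_eafs: Sequence[float] | None = None,
                 prefix: str = "ASV") -> list[SimTaxonSpec]:
    """A community of ``n`` taxa with Dirichlet abundances and uniform EAFs.

    GC contents are drawn in [0.35, 0.65] so that even fully labeled taxa
    stay inside the sequenced density window.  ``true_eafs`` overrides the
    uniform draw when supplied.
    """
    if true_eafs is None:
        eafs = rng.uniform(eaf_low, eaf_high, size=n)
    else:
        eafs = np.asarray(true_eafs, dtype=float)
        if len(eafs) != n:
            raise ValueError("true_eafs length must equal n")
    gcs = rng.uniform(0.35, 0.65, size=n)
    abund = rng.dirichlet(np.full(n, 5.0))
    taxa = []
    for i in range(n):
        phylum = _PHYLA[i % len(_PHYLA)]
        fam_idx = (i // len(_PHYLA)) % _FAMILIES_PER_PHYLUM
        taxa.append(SimTaxonSpec(
            taxon_id=f"{prefix}{i:04d}", gc=float(gcs[i]),
            true_eaf=float(eafs[i]), relative_abundance=float(abund[i]),
            phylum=phylum, family=f"{phylum}_fam{fam_idx}"))
    return taxa


def _simulate_tube(taxa: Sequence[SimTaxonSpec], config: SimConfig,
                   heavy: bool, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Copy matrix, read matrix and qPCR totals for one tube.

    Returns ``(copies, reads, qpcr)`` with shape (n_taxa, n_fractions) for
    the first two and (n_fractions,) for the totals.
    """
    grid = config.density_grid
    n_taxa = len(taxa)
    targets = np.array([t.heavy_wad if heavy else t.light_wad for t in taxa])
    targets = targets + rng.normal(0.0, config.tube_wad_jitter, size=n_taxa)
    disp = np.array([t.density_dispersion for t in taxa])
    outside = (targets < grid.min()) | (targets > grid.max())
    if outside.any():
        logger.warning("%d taxon target WAD(s) outside the density grid; "
                       "kernel mass renormalized", int(outside.sum()))
    # Gaussian density kernel, midpoint mass assignment, renormalized per taxon
    z2 = 0.5 * ((grid[None, :] - targets[:, None]) / disp[:, None]) ** 2
    # subtract the row minimum before exponentiating so point-mass kernels
    # (tiny dispersion) do not underflow to all-zero rows
    kernel = np.exp(-(z2 - z2.min(axis=1, keepdims=True)))
    kernel /= kernel.sum(axis=1, keepdims=True)
    totals = config.qpcr_total * np.array([t.relative_abundance for t in taxa])
    copies = totals[:, None] * kernel

    reads = np.zeros((n_taxa, config.n_fractions), dtype=np.int64)
    colsums = copies.sum(axis=0)
    for j in range(config.n_fractions):
        if colsums[j] > 0:
            reads[:, j] = rng.multinomial(config.read_depth,
                                          copies[:, j] / colsums[j])
    qpcr = colsums * rng.lognormal(0.0, config.qpcr_log_sd,
                                   size=config.n_fractions)
    return copies, reads, qpcr


def simulate_gradient_dataset(
    taxa_by_group: Mapping[tuple[str, str], Sequence[SimTaxonSpec]],
    config: SimConfig = SimConfig(),
    include_copies: bool = True,
) -> dict[str, pd.DataFrame]:
    """Simulate a full gradient-qSIP dataset with ground truth.

    ``taxa_by_group`` maps (site, temperature_treatment) to that group's
    community.  Returns the five canonical tables plus ``truth`` (true EAF
    and true RGR per taxon and group) and ``copies`` (the simulator's
    internal taxon-by-fraction copy matrix, long format, for consistency
    checks).
    """
    root = np.random.SeedSequence(config.seed)
    enrichment = mixed_water_enrichment(
        config.initial_water_mass, config.added_water_mass,
        tracer_af=config.tracer_atom_fraction)
    model = EnrichmentModel()

    frac_rows, feat_rows, tube_rows, water_rows = [], [], [], []
    truth_rows, copy_rows, tax_rows = [], [], []
    grid = SimConfig.density_grid.fget(config)

    for (site, treat) in sorted(taxa_by_group):
        taxa = list(taxa_by_group[(site, treat)])
        for t in taxa:
            tax_rows.append({"taxon_id": t.taxon_id, "phylum": t.phylum,
                             "class": f"{t.phylum}_class", "order": f"{t.phylum}_order",
                             "family": t.family, "genus": "", "species": ""})
            truth_rows.append({
                "taxon_id": t.taxon_id, "site": site,
                "temperature_treatment": treat, "gc": t.gc,
                "relative_abundance": t.relative_abundance,
                "true_eaf": t.true_eaf,
                "true_rgr": relative_growth_rate(
                    t.true_eaf, enrichment, model.oxygen_from_water_fraction,
                    model.incubation_days),
            })
        for plot in range(1, config.n_replicate_plots + 1):
            for iso in ("light", "heavy"):
                tube_id = f"{site}_{treat}_p{plot}_{iso}"
                rng = np.random.default_rng(root.spawn(1)[0])
                copies, reads, qpcr = _simulate_tube(
                    taxa, config, heavy=(iso == "heavy"), rng=rng)
                tube_rows.append({
                    "tube_id": tube_id, "site": site,
                    "temperature_treatment": treat, "isotope_treatment": iso,
                    "replicate_plot": f"{site}_{treat}_plot{plot}"})
                water_rows.append({
                    "tube_id": tube_id,
                    "initial_water_mass": config.initial_water_mass,
                    "added_water_mass": config.added_water_mass,
                    "added_atom_fraction": (config.tracer_atom_fraction
                                            if iso == "heavy"
                                            else qsip.NATURAL_18O_ABUNDANCE)})
                for j in range(config.n_fractions):
                    frac_rows.append({
                        "tube_id": tube_id, "fraction_index": j + 1,
                        "density": grid[j],
                        "dna_concentration": qpcr[j] / 5e7,
                        "gene_copies": qpcr[j]})
                ti, fj = np.nonzero(reads)
                for a, b in zip(ti, fj):
                    feat_rows.append({"taxon_id": taxa[a].taxon_id,
                                      "tube_id": tube_id,
                                      "fraction_index": int(b) + 1,
                                      "read_count": int(reads[a, b])})
                if include_copies:
                    ci, cj = np.nonzero(copies)
                    for a, b in zip(ci, cj):
                        copy_rows.append({
                            "taxon_id": taxa[a].taxon_id, "tube_id": tube_id,
                            "fraction_index": int(b) + 1,
                            "copies": copies[a, b]})

    return {
        "fractions": pd.DataFrame(frac_rows),
        "features": pd.DataFrame(feat_rows),
        "tubes": pd.DataFrame(tube_rows),
        "water": pd.DataFrame(water_rows),
        "taxonomy": pd.DataFrame(tax_rows).drop_duplicates("taxon_id")
                      .reset_index(drop=True),
        "truth": pd.DataFrame(truth_rows),
        "copies": pd.DataFrame(copy_rows),
    }


def simulate_flux_series(true_flux: float, config: ChamberConfig,
                         noise_sd: float = 0.0, seed: int = 0,
                         duration: float = 90.0, hz: float = 1.0,
                         c0: float = 400.0, w_start: float = 8.0,
                         w_rate: float = 0.01, mode: str = "ER",
                         plot_id: str = "plot1", day_index: int = 0) -> FluxSeries:
    """A chamber closure whose true flux is known (inverse of the flux chain).

    The dry CO2 trace is linear in time with the slope implied by
    ``true_flux`` at the water vapor mole fraction of the first retained
    sample; wet CO2 is reconstructed by re-applying the vapor dilution.
    Gaussian noise of ``noise_sd`` (umol mol^-1) is added to the dry trace.
    """
    t = np.linspace(0.0, duration, int(round(duration * hz)) + 1)
    w = w_start + w_rate * t
    keep = (t > config.deadband) & (t <= config.deadband + config.window)
    if not keep.any():
        raise ValueError("duration too short for deadband + window")
    w0 = float(w[keep][0])
    # invert flux = factor(w0) * slope
    slope = true_flux / flux_from_slope(1.0, config, w0)
    rng = np.random.default_rng(seed)
    c_dry = c0 + slope * t + rng.normal(0.0, noise_sd, size=len(t))
    c_wet = c_dry * (1.0 - w / 1000.0)
    return FluxSeries(timestamps=t, co2=c_wet, h2o=w, mode=mode,
                      plot_id=plot_id, day_index=day_index)
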