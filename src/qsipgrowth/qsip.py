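"""Per-taxon 18O excess atom fraction from density-gradient data.

The estimator follows the standard heavy-water qSIP chain.  For each taxon
and tube, reads are converted to absolute 16S copies by weighting the
fraction's qPCR total with the taxon's relative read abundance; the
copy-weighted mean buoyant density across fractions is the taxon's weighted
average density (WAD, ``W``).  The shift in WAD between tubes that received
natural-abundance water ("light") and 98 atom % 18O water ("heavy") is
converted to a DNA molecular-weight change via the empirical GC-density
calibration

    GC      = (W_light - 1.646057) / 0.083506
    M_light = 0.496 * GC + 307.691
    M_lab   = M_light * W_lab / W_light
    M_max   = M_light + 12.07747        (full 18O substitution)

and finally to the excess atom fraction of 18O:

    EAF = (M_lab - M_light) / (M_max - M_light) * (1 - 0.002000429)

where 0.002000429 is the natural abundance of 18O.  Confidence limits come
from resampling tubes (the independent experimental unit) with replacement
within each isotope treatment, 1000 iterations by default; a taxon is called
a significant grower when the 2.5th bootstrap percentile of EAF stays above
zero.  A taxon enters the analysis only if it is present (nonzero reads) in
at least ``min_fractions`` fractions of at least ``min_replicates`` tubes of
both isotope treatments within its (site, temperature) group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import DENSITY_WINDOW, flag_density_window, fraction_total_reads

logger = logging.getLogger("qsipgrowth")

# Natural abundance of 18O (atom fraction).
NATURAL_18O_ABUNDANCE: float = 0.002000429

# GC-content <-> buoyant density calibration and molecular-weight constants
# for the standard qSIP estimator chain.
GC_DENSITY_INTERCEPT: float = 1.646057   # g/ml, density of GC = 0 DNA
GC_DENSITY_SLOPE: float = 0.083506       # g/ml per unit GC fraction
MW_GC_SLOPE: float = 0.496               # g/mol per unit GC fraction
MW_INTERCEPT: float = 307.691            # g/mol, mean nucleotide weight at GC = 0
MW_FULL_18O_SHIFT: float = 12.07747      # g/mol gain at full 18O substitution

# Plausible buoyant density range of bacterial DNA; WADs outside trigger a
# warning and GC clamping rather than a hard error.
PLAUSIBLE_DENSITY_RANGE: tuple[float, float] = (1.6, 1.8)


@dataclass(frozen=True)
class MolecularWeights:
    """DNA molecular weights implied by light- and labeled-treatment WADs."""

    gc: float           # GC content fraction in [0, 1]
    m_light: float      # g/mol, unlabeled DNA
    m_lab: float        # g/mol, DNA in the labeled treatment
    m_heavy_max: float  # g/mol at full 18O substitution
    natural_18O_abundance: float = NATURAL_18O_ABUNDANCE


@dataclass(frozen=True)
class FilterCriteria:
    """Presence thresholds a taxon must meet within a (site, treatment) group."""

    min_fractions: int = 4
    min_replicates: int = 2
    require_both_isotopes: bool = True

    def __post_init__(self) -> None:
        if self.min_fractions < 1 or self.min_replicates < 1:
            raise ValueError("min_fractions and min_replicates must be >= 1")


@dataclass(frozen=True)
class EAFEstimate:
    taxon_id: str
    site: str
    temperature_treatment: str
    eaf_median: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_light: int
    n_heavy: int
    significant: bool
    draws: np.ndarray = field(repr=False, compare=False, default=None)


def taxon_copies_per_fraction(read_count, fraction_total_reads, fraction_gene_copies):
    """Absolute 16S copies of a taxon in one fraction (copies per g dry mass).

    Relative read abundance times the fraction's qPCR total.  Zero reads give
    zero copies regardless of the total; nonzero reads with a zero total are
    an invariant violation.
    """
    reads = np.asarray(read_count, dtype=float)
    totals = np.asarray(fraction_total_reads, dtype=float)
    copies = np.asarray(fraction_gene_copies, dtype=float)
    if np.any((reads > 0) & (totals <= 0)):
        raise ValueError("nonzero taxon reads in a fraction with zero total reads")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(reads > 0, reads / np.where(totals > 0, totals, 1.0) * copies, 0.0)
    return out if out.ndim else float(out)


def weighted_average_density(densities, copies) -> float:
    """Copy-weighted mean buoyant density; NaN when the taxon is absent."""
    d = np.asarray(densities, dtype=float)
    w = np.asarray(copies, dtype=float)
    total = w.sum()
    if total <= 0:
        return float("nan")
    return float(np.dot(d, w) / total)


def molecular_weights_from_wad(w_light: float, w_lab: float,
                               clamp_gc: bool = True) -> MolecularWeights:
    """Convert light/labeled WADs to the DNA molecular-weight chain.

    GC outside [0, 1] (noisy light WADs beyond the calibration range) is
    clamped with a warning when ``clamp_gc`` is set.
    """
    lo, hi = PLAUSIBLE_DENSITY_RANGE
    for name, w in (("light", w_light), ("labeled", w_lab)):
        if not lo <= w <= hi:
            logger.warning("%s WAD %.4f g/ml outside plausible DNA density "
                           "range [%g, %g]", name, w, lo, hi)
    gc = (w_light - GC_DENSITY_INTERCEPT) / GC_DENSITY_SLOPE
    if clamp_gc and not 0.0 <= gc <= 1.0:
        logger.warning("GC content %.3f outside [0, 1]; clamping", gc)
        gc = min(max(gc, 0.0), 1.0)
    m_light = MW_GC_SLOPE * gc + MW_INTERCEPT
    m_lab = m_light * (1.0 + (w_lab - w_light) / w_light)
    return MolecularWeights(gc=gc, m_light=m_light, m_lab=m_lab,
                            m_heavy_max=m_light + MW_FULL_18O_SHIFT)


def excess_atom_fraction(mw: MolecularWeights) -> float:
    """18O excess atom fraction; negative when the labeled WAD sits below light."""
    return ((mw.m_lab - mw.m_light) / (mw.m_heavy_max - mw.m_light)
            * (1.0 - mw.natural_18O_abundance))


def eaf_from_wads(w_light, w_lab):
    """Vectorized light/labeled WAD -> EAF (GC clamped to [0, 1] silently).

    Same chain as :func:`molecular_weights_from_wad` +
    :func:`excess_atom_fraction`, usable on arrays inside the bootstrap.
    """
    w_light = np.asarray(w_light, dtype=float)
    w_lab = np.asarray(w_lab, dtype=float)
    gc = np.clip((w_light - GC_DENSITY_INTERCEPT) / GC_DENSITY_SLOPE, 0.0, 1.0)
    m_light = MW_GC_SLOPE * gc + MW_INTERCEPT
    m_lab = m_light * (w_lab / w_light)
    return (m_lab - m_light) / MW_FULL_18O_SHIFT * (1.0 - NATURAL_18O_ABUNDANCE)


# ---------------------------------------------------------------------------
# per-taxon tube profiles (WAD table)
# ---------------------------------------------------------------------------

def taxon_tube_wads(features: pd.DataFrame, fractions: pd.DataFrame,
                    window: tuple[float, float] = DENSITY_WINDOW) -> pd.DataFrame:
    """WAD and total copies per (taxon, tube) from in-window fractions.

    Returns columns ``taxon_id, tube_id, wad, total_copies``; taxa absent
    from a tube simply have no row.
    """
    frac = fractions
    if "in_window" not in frac.columns:
        frac = flag_density_window(frac, window)
    frac = frac[frac["in_window"]]
    totals = fraction_total_reads(features)
    df = features.merge(totals, on=["tube_id", "fraction_index"])
    df = df.merge(frac[["tube_id", "fraction_index", "density", "gene_copies"]],
                  on=["tube_id", "fraction_index"], how="inner")
    if df.empty:
        return pd.DataFrame(columns=["taxon_id", "tube_id", "wad", "total_copies"])
    df["copies"] = taxon_copies_per_fraction(
        df["read_count"], df["total_reads"], df["gene_copies"])
    grouped = df.groupby(["taxon_id", "tube_id"])
    out = grouped.apply(
        lambda g: pd.Series({
            "wad": weighted_average_density(g["density"], g["copies"]),
            "total_copies": g["copies"].sum(),
        }),
        include_groups=False,
    ).reset_index()
    return out[out["total_copies"] > 0].reset_index(drop=True)


# ---------------------------------------------------------------------------
# presence filter
# ---------------------------------------------------------------------------

def filter_taxa(features: pd.DataFrame, tubes: pd.DataFrame,
                criteria: FilterCriteria = FilterCriteria(),
                fractions: pd.DataFrame | None = None) -> dict[tuple[str, str], set[str]]:
    """Taxa passing the presence criteria per (site, temperature) group.

    A taxon passes for a group iff for each isotope treatment there are at
    least ``min_replicates`` tubes in which it has nonzero reads in at least
    ``min_fractions`` distinct (in-window) fractions.
    """
    feats = features[features["read_count"] > 0]
    if fractions is not None:
        frac = fractions
        if "in_window" not in frac.columns:
            frac = flag_density_window(frac)
        keep = frac.loc[frac["in_window"], ["tube_id", "fraction_index"]]
        feats = feats.merge(keep, on=["tube_id", "fraction_index"])

    meta = tubes.set_index("tube_id")
    groups = tubes.groupby(["site", "temperature_treatment"])
    isotopes = ("light", "heavy") if criteria.require_both_isotopes else None

    # fractions-per-tube occupancy per taxon
    occ = (feats.groupby(["taxon_id", "tube_id"])["fraction_index"]
           .nunique().rename("n_fractions").reset_index())
    occ = occ[occ["n_fractions"] >= criteria.min_fractions]
    occ = occ.merge(meta[["site", "temperature_treatment", "isotope_treatment"]],
                    left_on="tube_id", right_index=True)

    result: dict[tuple[str, str], set[str]] = {}
    for (site, treat), gtubes in groups:
        need = isotopes if isotopes else tuple(gtubes["isotope_treatment"].unique())
        for iso in ("light", "heavy"):
            if iso in (need or ()) and not (gtubes["isotope_treatment"] == iso).any():
                raise ValueError(
                    f"group ({site}, {treat}) has no {iso}-water tubes")
        sub = occ[(occ["site"] == site) & (occ["temperature_treatment"] == treat)]
        counts = (sub.groupby(["taxon_id", "isotope_treatment"])["tube_id"]
                  .nunique().unstack(fill_value=0))
        passed: set[str] = set()
        if len(counts):
            ok = np.ones(len(counts), dtype=bool)
            for iso in need:
                ok &= (counts.get(iso, pd.Series(0, index=counts.index))
                       >= criteria.min_replicates).to_numpy()
            passed = set(counts.index[ok])
        result[(site, treat)] = passed
    return result


# ---------------------------------------------------------------------------
# bootstrap EAF
# ---------------------------------------------------------------------------

def bootstrap_eaf_draws(light_wads: np.ndarray, heavy_wads: np.ndarray,
                        n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """EAF per bootstrap iteration, resampling tubes within isotope treatment."""
    light = np.asarray(light_wads, dtype=float)
    heavy = np.asarray(heavy_wads, dtype=float)
    li = rng.integers(0, len(light), size=(n_boot, len(light)))
    hi = rng.integers(0, len(heavy), size=(n_boot, len(heavy)))
    w_light = light[li].mean(axis=1)
    w_heavy = heavy[hi].mean(axis=1)
    return eaf_from_wads(w_light, w_heavy)


def bootstrap_eaf(taxon_id: str, site: str, temperature_treatment: str,
                  light_wads, heavy_wads, n_boot: int = 1000,
                  seed: int | np.random.SeedSequence | np.random.Generator = 0,
                  keep_draws: bool = True) -> EAFEstimate:
    """Median EAF with a 95 % percentile bootstrap CI for one taxon/group.

    Deterministic for a fixed seed and ``n_boot``.  ``significant`` is strict:
    the lower confidence limit must lie above zero.
    """
    light = np.asarray(light_wads, dtype=float)
    heavy = np.asarray(heavy_wads, dtype=float)
    light, heavy = light[~np.isnan(light)], heavy[~np.isnan(heavy)]
    if len(light) == 0 or len(heavy) == 0:
        raise ValueError(
            f"taxon {taxon_id}: no defined WAD in one isotope treatment")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    draws = bootstrap_eaf_draws(light, heavy, n_boot, rng)
    ci_low, ci_high = np.percentile(draws, [2.5, 97.5])
    return EAFEstimate(
        taxon_id=taxon_id, site=site, temperature_treatment=temperature_treatment,
        eaf_median=float(np.median(draws)), ci_low=float(ci_low),
        ci_high=float(ci_high), n_boot=n_boot,
        n_light=len(light), n_heavy=len(heavy),
        significant=bool(ci_low > 0),
        draws=draws if keep_draws else None,
    )


def per_replicate_eaf(heavy_wads, light_wads):
    """One EAF per heavy tube against the mean light WAD (replicate-level)."""
    heavy = np.asarray(heavy_wads, dtype=float)
    light = np.asarray(light_wads, dtype=float)
    light = light[~np.isnan(light)]
    if len(light) == 0:
        raise ValueError("no defined light-tube WAD")
    return eaf_from_wads(np.full_like(heavy, light.mean()), heavy)
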