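"""Growth rates and community aggregates from excess atom fraction.

Excess atom fraction is converted to a relative growth rate (RGR, day^-1)
by dividing by the maximum enrichment a fully-grown taxon could reach over
the incubation: the average 18O atom fraction of soil water during the
tracer period times the fraction of DNA oxygen drawn from water (0.6) times
the incubation length in days.  Soil-water enrichment comes from a two-pool
mixing model of the water initially in the core (natural abundance) and the
added tracer water.  RGR assumes populations at steady state and does not
correct for taxon turnover, which biases it low.

Community-level quantities: cumulative growth is the sum over taxa of
RGR x 16S gene copies per g dry mass (new copies per gram per day); phylum
contributions are each phylum's share of that sum.  The warming-response
test subtracts, per bootstrap iteration, a family's mean RGR in control
plots from its mean RGR in warmed plots and calls the family a warming
responder when the 95 % percentile interval of the differences stays above
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .qsip import NATURAL_18O_ABUNDANCE

TRACER_ATOM_FRACTION: float = 0.98        # 18O atom fraction of added tracer water
OXYGEN_FROM_WATER_FRACTION: float = 0.6   # fraction of DNA oxygen derived from water
INCUBATION_DAYS: float = 28.0


@dataclass(frozen=True)
class EnrichmentModel:
    """Soil-water 18O enrichment parameters for the RGR denominator."""

    natural_atom_fraction: float = NATURAL_18O_ABUNDANCE
    tracer_atom_fraction: float = TRACER_ATOM_FRACTION
    oxygen_from_water_fraction: float = OXYGEN_FROM_WATER_FRACTION
    incubation_days: float = INCUBATION_DAYS

    def __post_init__(self) -> None:
        if not 0 < self.oxygen_from_water_fraction <= 1:
            raise ValueError("oxygen_from_water_fraction must be in (0, 1]")
        if self.incubation_days <= 0:
            raise ValueError("incubation_days must be positive")


@dataclass(frozen=True)
class FamilyWarmingTest:
    family: str
    site: str
    diff_median: float  # day^-1, warmed - control
    ci_low: float
    ci_high: float
    n_boot: int
    increased_with_warming: bool


def mixed_water_enrichment(initial_mass: float, added_mass: float,
                           natural_af: float = NATURAL_18O_ABUNDANCE,
                           tracer_af: float = TRACER_ATOM_FRACTION) -> float:
    """18O atom fraction of soil water after tracer addition (mass-weighted)."""
    if initial_mass < 0 or added_mass < 0:
        raise ValueError("water masses must be non-negative")
    total = initial_mass + added_mass
    if total == 0:
        raise ValueError("initial and added water mass are both zero")
    return (initial_mass * natural_af + added_mass * tracer_af) / total


def relative_growth_rate(eaf, enrichment: float,
                         oxygen_from_water: float = OXYGEN_FROM_WATER_FRACTION,
                         days: float = INCUBATION_DAYS):
    """RGR (day^-1) = EAF / (soil-water enrichment * 0.6 * days)."""
    if enrichment <= 0:
        raise ValueError("soil-water enrichment must be positive")
    if days <= 0:
        raise ValueError("incubation length must be positive")
    eaf = np.asarray(eaf, dtype=float)
    out = eaf / (enrichment * oxygen_from_water * days)
    return out if out.ndim else float(out)


def cumulative_growth(records: pd.DataFrame) -> float:
    """Total community growth: sum over taxa of RGR x gene copies.

    ``records`` needs columns ``rgr`` (day^-1) and ``gene_copies``
    (copies per g dry mass); returns copies g^-1 day^-1.
    """
    return float((records["rgr"] * records["gene_copies"]).sum())


def phylum_contributions(records: pd.DataFrame) -> dict[str, float]:
    """Each phylum's proportion of cumulative growth (sums to 1).

    Taxa lacking a phylum rank are pooled as "Unclassified".  Raises if
    total growth is not positive, in which case proportions are undefined.
    """
    growth = records["rgr"] * records["gene_copies"]
    phyla = records["phylum"] if "phylum" in records.columns else pd.Series(
        pd.NA, index=records.index)
    phyla = phyla.fillna("Unclassified").replace("", "Unclassified")
    totals = growth.groupby(phyla.to_numpy()).sum()
    total = totals.sum()
    if total <= 0:
        raise ValueError("total community growth is not positive; "
                         "phylum proportions undefined")
    return {str(p): float(v / total) for p, v in totals.items()}


def family_warming_response(
    control_draws: Mapping[str, np.ndarray],
    warmed_draws: Mapping[str, np.ndarray],
    asv_family: Mapping[str, str],
    site: str,
    n_boot: int | None = None,
) -> list[FamilyWarmingTest]:
    """Bootstrap test of family-level RGR increase under warming at one site.

    ``control_draws`` / ``warmed_draws`` map ASV id -> per-iteration bootstrap
    RGR draws (aligned length).  Family RGR per iteration is the unweighted
    mean over that treatment's ASVs in the family; families estimable in only
    one treatment are excluded.  Differences are warmed - control.
    """
    fam_asvs: dict[str, dict[str, list[str]]] = {}
    for arm, draws in (("control", control_draws), ("warmed", warmed_draws)):
        for asv in draws:
            fam = asv_family.get(asv)
            if fam is None or (isinstance(fam, float) and np.isnan(fam)) or fam == "":
                continue
            fam_asvs.setdefault(str(fam), {"control": [], "warmed": []})[arm].append(asv)

    results: list[FamilyWarmingTest] = []
    for fam in sorted(fam_asvs):
        arms = fam_asvs[fam]
        if not arms["control"] or not arms["warmed"]:
            continue
        ctl = np.mean([np.asarray(control_draws[a], float) for a in arms["control"]],
                      axis=0)
        wrm = np.mean([np.asarray(warmed_draws[a], float) for a in arms["warmed"]],
                      axis=0)
        nb = n_boot or len(ctl)
        diff = wrm[:nb] - ctl[:nb]
        ci_low, ci_high = np.percentile(diff, [2.5, 97.5])
        results.append(FamilyWarmingTest(
            family=fam, site=site, diff_median=float(np.median(diff)),
            ci_low=float(ci_low), ci_high=float(ci_high), n_boot=len(diff),
            increased_with_warming=bool(ci_low > 0)))
    return results
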