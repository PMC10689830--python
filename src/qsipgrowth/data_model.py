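"""Domain tables and I/O for density-gradient qSIP data.

The pipeline works on five tidy tables, each carried as a
:class:`pandas.DataFrame` with fixed canonical column names:

``fractions``
    one row per gradient fraction of one ultracentrifuge tube —
    ``tube_id``, ``fraction_index`` (1-based from the heaviest fraction),
    ``density`` (g/ml), ``dna_concentration`` (ng/ul) and ``gene_copies``
    (16S rRNA copies per g dry mass, from qPCR).
``features``
    long-format ASV read counts per (tube, fraction) — the amplicon
    feature table exported from upstream denoising.
``tubes``
    tube metadata: successional ``site`` (early/late), ``temperature_treatment``
    (control/warmed), ``isotope_treatment`` (light = natural-abundance water,
    heavy = 98 atom % 18O water) and ``replicate_plot``.
``water``
    per-tube water-addition records used by the soil-water mixing model.
``taxonomy``
    ordered ranks phylum..species per ASV (possibly partial).

All downstream per-taxon calculations use only fractions whose buoyant
density lies inside the sequenced window (1.65-1.74 g/ml by default);
:func:`flag_density_window` marks rows accordingly.

Interchange format is tab-separated UTF-8 with a header row.  Readers accept
an optional header mapping (canonical name -> file column name) so foreign
column spellings can be ingested without rewriting files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("qsipgrowth")

# Density window actually sequenced; fractions outside are flagged and
# excluded from all per-taxon calculations.
DENSITY_WINDOW: tuple[float, float] = (1.65, 1.74)

TAXONOMY_RANKS: tuple[str, ...] = (
    "phylum", "class", "order", "family", "genus", "species"
)

FRACTION_COLUMNS = (
    "tube_id", "fraction_index", "density", "dna_concentration", "gene_copies"
)
FEATURE_COLUMNS = ("taxon_id", "tube_id", "fraction_index", "read_count")
TUBE_COLUMNS = (
    "tube_id", "site", "temperature_treatment", "isotope_treatment",
    "replicate_plot",
)
WATER_COLUMNS = (
    "tube_id", "initial_water_mass", "added_water_mass", "added_atom_fraction"
)
TAXONOMY_COLUMNS = ("taxon_id",) + TAXONOMY_RANKS


class Site(str, Enum):
    EARLY = "early"
    LATE = "late"


class TemperatureTreatment(str, Enum):
    CONTROL = "control"
    WARMED = "warmed"


class IsotopeTreatment(str, Enum):
    """Water-addition isotope label of a tube."""

    LIGHT = "light"   # natural-abundance water
    HEAVY = "heavy"   # 98 atom % 18O water


class ParseError(ValueError):
    """A required column is missing or a file cannot be interpreted."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


@dataclass(frozen=True)
class TubeMeta:
    tube_id: str
    site: str
    temperature_treatment: str
    isotope_treatment: str
    replicate_plot: str


@dataclass(frozen=True)
class FractionRecord:
    """One gradient fraction of one tube."""

    tube_id: str
    fraction_index: int
    density: float
    dna_concentration: float
    gene_copies: float


@dataclass(frozen=True)
class WaterAddition:
    tube_id: str
    initial_water_mass: float  # g, water initially in the core
    added_water_mass: float    # g, tracer (or natural) water added
    added_atom_fraction: float  # 18O atom fraction of the added water


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str],
              columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a delimited table, rename per the header mapping, check columns.

    ``columns`` maps canonical name -> column name in the file.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if columns:
        rename = {v: k for k, v in columns.items()}
        df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    return df


def read_fraction_table(path: str | Path,
                        columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read per-fraction density / DNA / qPCR data; row order is preserved."""
    df = _read_tsv(path, FRACTION_COLUMNS, columns)
    df = df.loc[:, list(FRACTION_COLUMNS)]
    df["fraction_index"] = df["fraction_index"].astype(int)
    for col in ("density", "dna_concentration", "gene_copies"):
        df[col] = df[col].astype(float)
    validate_fractions(df)
    return df


def read_feature_table(path: str | Path, tubes: pd.DataFrame | None = None,
                       columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an ASV-by-fraction feature table, long or wide.

    Long format has the canonical columns.  Wide format is a taxa x samples
    matrix whose first column is ``taxon_id`` and whose remaining column names
    are ``<tube_id>:<fraction_index>`` sample identifiers; when ``tubes`` is
    given every referenced tube_id must exist in it.  Zero counts are dropped
    (sparse long storage); column sums are preserved by construction.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if columns:
        df = df.rename(columns={v: k for k, v in columns.items()})
    if set(FEATURE_COLUMNS).issubset(df.columns):
        long = df.loc[:, list(FEATURE_COLUMNS)].copy()
    else:
        if "taxon_id" not in df.columns:
            raise ParseError(f"{path}: neither long feature columns nor a "
                             "'taxon_id' wide-matrix column present")
        long = df.melt(id_vars="taxon_id", var_name="sample_id",
                       value_name="read_count")
        if long.empty:
            return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                FEATURE_COLUMNS, (str, str, int, np.int64))})
        parts = long["sample_id"].str.rsplit(":", n=1, expand=True)
        if parts.shape[1] != 2 or parts.isna().any().any():
            bad = long.loc[parts.isna().any(axis=1), "sample_id"].unique()
            raise ParseError(
                f"{path}: sample identifier(s) {list(bad)[:5]} not decomposable "
                "into tube_id:fraction_index")
        long["tube_id"] = parts[0]
        long["fraction_index"] = parts[1].astype(int)
        long = long.loc[:, list(FEATURE_COLUMNS)]
    long["read_count"] = long["read_count"].astype(np.int64)
    long = long[long["read_count"] != 0].reset_index(drop=True)
    if tubes is not None:
        known = set(tubes["tube_id"])
        unknown = sorted(set(long["tube_id"]) - known)
        if unknown:
            raise ParseError(
                f"{path}: sample tube id(s) {unknown[:5]} absent from tube metadata")
    validate_features(long)
    return long


def read_tube_table(path: str | Path,
                    columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _read_tsv(path, TUBE_COLUMNS, columns).loc[:, list(TUBE_COLUMNS)]
    for col, enum in (("site", Site),
                      ("temperature_treatment", TemperatureTreatment),
                      ("isotope_treatment", IsotopeTreatment)):
        df[col] = df[col].astype(str)
        bad = sorted(set(df[col]) - {e.value for e in enum})
        if bad:
            raise ValidationError(f"invalid {col} value(s): {bad}")
    validate_tubes(df)
    return df


def read_water_table(path: str | Path,
                     columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _read_tsv(path, WATER_COLUMNS, columns).loc[:, list(WATER_COLUMNS)]
    for col in WATER_COLUMNS[1:]:
        df[col] = df[col].astype(float)
    validate_water(df)
    return df


def read_taxonomy_table(path: str | Path,
                        columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = _read_tsv(path, ("taxon_id",), columns)
    for rank in TAXONOMY_RANKS:
        if rank not in df.columns:
            df[rank] = pd.NA
    return df.loc[:, list(TAXONOMY_COLUMNS)]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_fractions(df: pd.DataFrame) -> None:
    if (df["density"] <= 0).any():
        bad = df.loc[df["density"] <= 0, "density"].iloc[0]
        raise ValidationError(f"non-positive fraction density {bad!r}")
    if (df["dna_concentration"] < 0).any() or (df["gene_copies"] < 0).any():
        raise ValidationError("negative DNA concentration or gene copies")
    if (df["fraction_index"] < 1).any():
        raise ValidationError("fraction_index must be >= 1")
    if df.duplicated(["tube_id", "fraction_index"]).any():
        dup = df[df.duplicated(["tube_id", "fraction_index"])].iloc[0]
        raise ValidationError(
            f"duplicate fraction {dup['fraction_index']} in tube {dup['tube_id']}")


def validate_features(df: pd.DataFrame) -> None:
    if (df["read_count"] < 0).any():
        raise ValidationError("negative read counts")
    if df.duplicated(["taxon_id", "tube_id", "fraction_index"]).any():
        raise ValidationError("duplicate (taxon, tube, fraction) feature rows")


def validate_tubes(df: pd.DataFrame) -> None:
    if df.duplicated("tube_id").any():
        raise ValidationError("duplicate tube_id in tube metadata")
    key = ["site", "temperature_treatment", "isotope_treatment", "replicate_plot"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key)].iloc[0]
        raise ValidationError(
            f"tube metadata not unique for {tuple(dup[key])}")


def validate_water(df: pd.DataFrame) -> None:
    if (df["initial_water_mass"] < 0).any() or (df["added_water_mass"] < 0).any():
        raise ValidationError("negative water mass")
    af = df["added_atom_fraction"]
    if ((af < 0) | (af > 1)).any():
        raise ValidationError("added_atom_fraction outside [0, 1]")


def flag_density_window(fractions: pd.DataFrame,
                        window: tuple[float, float] = DENSITY_WINDOW) -> pd.DataFrame:
    """Return a copy with an ``in_window`` flag for the sequenced density range."""
    out = fractions.copy()
    lo, hi = window
    out["in_window"] = (out["density"] >= lo) & (out["density"] <= hi)
    n_out = int((~out["in_window"]).sum())
    if n_out:
        logger.warning("%d fraction(s) outside density window [%g, %g] excluded "
                       "from per-taxon calculations", n_out, lo, hi)
    return out


def fraction_total_reads(features: pd.DataFrame) -> pd.DataFrame:
    """Total reads per (tube, fraction) sample — the feature-table column sums."""
    totals = (features.groupby(["tube_id", "fraction_index"], as_index=False)
              ["read_count"].sum()
              .rename(columns={"read_count": "total_reads"}))
    return totals


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a canonical table as TSV (CSV if the suffix says so)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)
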