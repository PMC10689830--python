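"""Closed-chamber CO2 flux: dry-mole-fraction correction, slope, and flux.

A transparent chamber measures net ecosystem exchange (NEE); darkened, it
measures ecosystem respiration (ER).  The analyzer's CO2 mole fraction C
(umol mol^-1) is first corrected to a dry mole fraction using the water
vapor mole fraction W (mmol mol^-1):

    C_dry = C / (1 - W/1000)

The first ``deadband`` seconds (20 s default) after chamber closure are
discarded, then C_dry is regressed on time over the next ``window`` seconds
(70 s default) by ordinary least squares.  The slope converts to an areal
flux (umol CO2 m^-2 s^-1):

    flux = 10 * V_tot * P * (1 - W0/1000) / (A * R * T) * dC_dry/dt

with chamber volume V_tot in cm^3 (base volume plus collar headspace),
pressure P in kPa, chamber footprint A in cm^2, R = 8.31 J K^-1 mol^-1,
temperature T in K, and W0 the water vapor mole fraction at the first
retained sample after the deadband.  The leading 10 reconciles the mixed
units.  Sign conventions follow the atmospheric perspective: accumulation
in the chamber is a positive flux, so negative NEE marks a carbon sink, and
gross ecosystem productivity is GEP = -NEE + ER.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy import stats

logger = logging.getLogger("qsipgrowth")

GAS_CONSTANT: float = 8.31        # J K^-1 mol^-1
CHAMBER_BASE_VOLUME: float = 5700.0   # cm^3 (5.7 l chamber)
CHAMBER_FOOTPRINT: float = 660.5      # cm^2
DEFAULT_DEADBAND: float = 20.0        # s discarded after closure
DEFAULT_WINDOW: float = 70.0          # s regressed after the deadband


@dataclass(frozen=True)
class ChamberConfig:
    """Geometry and ambient conditions for one chamber measurement."""

    pressure: float                   # kPa
    temperature: float                # K
    collar_height: float = 3.0        # cm of collar above the soil surface
    base_volume: float = CHAMBER_BASE_VOLUME    # cm^3
    footprint_area: float = CHAMBER_FOOTPRINT   # cm^2
    gas_constant: float = GAS_CONSTANT
    deadband: float = DEFAULT_DEADBAND          # s
    window: float = DEFAULT_WINDOW              # s

    def __post_init__(self) -> None:
        for name in ("pressure", "temperature", "base_volume", "footprint_area",
                     "gas_constant"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.collar_height < 0:
            raise ValueError("collar_height must be non-negative")

    @property
    def v_tot(self) -> float:
        """Chamber volume (cm^3) adjusted for the collar headspace."""
        return self.base_volume + self.collar_height * self.footprint_area


@dataclass(frozen=True)
class FluxSeries:
    """One chamber closure: concentration time series and its mode."""

    timestamps: np.ndarray   # s, strictly increasing
    co2: np.ndarray          # umol mol^-1 (wet)
    h2o: np.ndarray          # mmol mol^-1
    mode: str                # "NEE" (transparent) or "ER" (darkened)
    plot_id: str = ""
    day_index: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "co2", np.asarray(self.co2, dtype=float))
        object.__setattr__(self, "h2o", np.asarray(self.h2o, dtype=float))
        if len(t) != len(self.co2) or len(t) != len(self.h2o):
            raise ValueError("timestamps, co2 and h2o must be the same length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.mode not in ("NEE", "ER"):
            raise ValueError(f"mode must be 'NEE' or 'ER', got {self.mode!r}")


@dataclass(frozen=True)
class FluxResult:
    plot_id: str
    day_index: int
    mode: str
    slope: float   # umol mol^-1 s^-1 of dry CO2
    w0: float      # mmol mol^-1 at the first retained sample
    flux: float    # umol CO2 m^-2 s^-1


def dry_co2(c, w):
    """Dry CO2 mole fraction (umol mol^-1) from wet CO2 and water vapor."""
    c = np.asarray(c, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w >= 1000):
        raise ValueError("water vapor mole fraction must be < 1000 mmol mol^-1")
    out = c / (1.0 - w / 1000.0)
    return out if out.ndim else float(out)


def trim_and_slope(series: FluxSeries,
                   config: ChamberConfig) -> tuple[float, float]:
    """OLS slope of dry CO2 vs time over the post-deadband window.

    Returns ``(slope, w0)`` where w0 is the water vapor mole fraction at the
    first retained sample (time 0 of the regression).  Uses the recorded
    timestamps, not an assumed sampling rate.
    """
    t = series.timestamps - series.timestamps[0]
    required = config.deadband + config.window
    if t[-1] < required:
        raise ValueError(
            f"series spans {t[-1]:.1f} s but deadband + window require "
            f"{required:.1f} s")
    keep = (t > config.deadband) & (t <= config.deadband + config.window)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 samples in the regression window")
    cdry = dry_co2(series.co2[keep], series.h2o[keep])
    fit = stats.linregress(t[keep], cdry)
    w0 = float(series.h2o[keep][0])
    return float(fit.slope), w0


def flux_from_slope(slope: float, config: ChamberConfig, w0: float) -> float:
    """Areal CO2 flux (umol m^-2 s^-1) from the dry-CO2 slope."""
    factor = (10.0 * config.v_tot * config.pressure * (1.0 - w0 / 1000.0)
              / (config.footprint_area * config.gas_constant * config.temperature))
    return factor * slope


def compute_flux(series: FluxSeries, config: ChamberConfig) -> FluxResult:
    """Full chain for one chamber closure: trim, regress, convert."""
    slope, w0 = trim_and_slope(series, config)
    flux = flux_from_slope(slope, config, w0)
    if series.mode == "ER" and flux < 0:
        logger.warning("negative ER flux %.4f for plot %s day %d",
                       flux, series.plot_id, series.day_index)
    return FluxResult(plot_id=series.plot_id, day_index=series.day_index,
                      mode=series.mode, slope=slope, w0=w0, flux=flux)


def gep(er: float, nee: float) -> float:
    """Gross ecosystem productivity: NEE negated, then ER added."""
    return -nee + er


def flux_table(results: Iterable[FluxResult]):
    """Pair ER and NEE closures per (plot, day) into an ER/NEE/GEP table.

    GEP is left missing (NaN) when either member of the pair is absent.
    Returns a pandas DataFrame with one row per plot-day.
    """
    import pandas as pd

    rows = {}
    for r in results:
        key = (r.plot_id, r.day_index)
        entry = rows.setdefault(key, {"plot_id": r.plot_id, "day_index": r.day_index,
                                      "ER": np.nan, "NEE": np.nan,
                                      "slope_ER": np.nan, "slope_NEE": np.nan})
        entry[r.mode] = r.flux
        entry[f"slope_{r.mode}"] = r.slope
    df = pd.DataFrame(sorted(rows.values(), key=lambda e: (e["plot_id"], e["day_index"])))
    if len(df):
        df["GEP"] = np.where(df["ER"].notna() & df["NEE"].notna(),
                             -df["NEE"] + df["ER"], np.nan)
    else:
        df = pd.DataFrame(columns=["plot_id", "day_index", "ER", "NEE",
                                   "slope_ER", "slope_NEE", "GEP"])
    return df
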