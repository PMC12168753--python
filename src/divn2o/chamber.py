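"""Static-chamber N2O flux computation.

Converts closed-chamber headspace concentration time series (ppb N2O,
sampled by default at 0/10/20/30/40 min) into soil-atmosphere fluxes in
ug N2O m-2 h-1, applies the terrain slope-factor correction
S = (theta/10)**0.78, and aggregates fluxes by season and tree-diversity
level.

Unit chain
----------
The concentration slope dC/dt is obtained by ordinary least squares over
all time points, in ppb min-1 (ppb = nmol N2O per mol air).  With the
ideal-gas N2O density rho(T, P) in g m-3, the flux is

    f = rho * h * dC/dt * 1e-9 [ppb -> mole fraction]
                        * 60   [min -> h]
                        * 1e6  [g -> ug]

i.e. ``f = rho * h * slope * 6e-2`` in ug m-2 h-1 for h in metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChamberSeries",
    "FluxEstimate",
    "n2o_density",
    "chamber_flux",
    "slope_factor",
    "apply_slope_correction",
    "seasonal_aggregate",
    "diversity_level_test",
    "GROWING_MONTHS",
]

M_N2O = 44.013  # g mol-1
R_GAS = 8.314462618  # J mol-1 K-1
STANDARD_PRESSURE = 101325.0  # Pa

#: Growing season months (April-October); the complement is non-growing.
GROWING_MONTHS = frozenset(range(4, 11))

# ppb min-1 -> (mole fraction) h-1 -> ug m-2 h-1 together with rho*h
_PPB_MIN_TO_UG_FACTOR = 1e-9 * 60.0 * 1e6


@dataclass
class ChamberSeries:
    """One chamber deployment: timed headspace concentrations plus geometry.

    Parameters
    ----------
    times : minutes since chamber closure, strictly increasing, >= 3 points.
    concentrations : N2O mole fraction in ppb at each time.
    chamber_height : m. ``volume``/``base_area`` may be given redundantly;
        when all three are present they must satisfy v = A*h within 1%.
    air_temperature : deg C inside the chamber.
    """

    times: Sequence[float]
    concentrations: Sequence[float]
    chamber_height: float
    air_temperature: float
    base_area: float | None = None
    volume: float | None = None
    pressure: float = STANDARD_PRESSURE
    plot_id: str = ""
    richness: int | None = None
    date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.size < 3:
            raise ValueError("ChamberSeries requires >= 3 time points")
        if t.size != c.size:
            raise ValueError("times and concentrations must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.chamber_height <= 0:
            raise ValueError("chamber_height must be positive")
        if self.base_area is not None and self.volume is not None:
            expected = self.base_area * self.chamber_height
            if expected > 0 and abs(self.volume - expected) > 0.01 * expected:
                raise ValueError(
                    "volume inconsistent with base_area * chamber_height "
                    f"({self.volume:g} vs {expected:g} m^3)"
                )
        self.times = t
        self.concentrations = c


@dataclass
class FluxEstimate:
    """Flux plus fit diagnostics for one chamber deployment."""

    flux: float  # ug N2O m-2 h-1
    slope: float  # ppb min-1
    fit_r_squared: float
    density: float  # g m-3 at chamber temperature
    corrected: bool = False
    slope_angle: float | None = None  # degrees, when correction applied
    quality_ok: bool = True
    plot_id: str = ""
    richness: int | None = None
    date: pd.Timestamp | None = None


def n2o_density(temperature: float, pressure: float = STANDARD_PRESSURE) -> float:
    """Ideal-gas density of pure N2O, g m-3, at chamber temperature (deg C)."""
    if temperature <= -273.15:
        raise ValueError(f"nonphysical temperature {temperature} degC")
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    t_kelvin = temperature + 273.15
    return pressure * M_N2O / (R_GAS * t_kelvin)


def chamber_flux(series: ChamberSeries, r2_threshold: float = 0.90) -> FluxEstimate:
    """N2O flux from the OLS concentration slope: f = rho * h * dC/dt.

    Fits with r-squared below ``r2_threshold`` are flagged
    (``quality_ok=False``) but never dropped.  A perfectly constant series
    has slope 0, flux 0 and, by convention, r-squared 1 (no misfit).
    """
    t = series.times
    c = series.concentrations
    if np.ptp(c) == 0:  # constant headspace: exactly zero flux
        slope, intercept = 0.0, float(c[0])
    else:
        slope, intercept = np.polyfit(t, c, 1)
    resid = c - (slope * t + intercept)
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    rho = n2o_density(series.air_temperature, series.pressure)
    flux = rho * series.chamber_height * slope * _PPB_MIN_TO_UG_FACTOR
    return FluxEstimate(
        flux=flux,
        slope=float(slope),
        fit_r_squared=r2,
        density=rho,
        quality_ok=r2 >= r2_threshold,
        plot_id=series.plot_id,
        richness=series.richness,
        date=series.date,
    )


def slope_factor(theta: float) -> float:
    """Terrain slope factor S = (theta/10)**0.78 for slope angle theta (deg)."""
    if theta < 0:
        raise ValueError("slope angle must be >= 0 degrees")
    return (theta / 10.0) ** 0.78


def apply_slope_correction(value: float, theta: float, mode: str = "multiply") -> float:
    """Adjust a plot-level quantity for terrain slope.

    ``mode='multiply'`` (default) returns value*S; ``mode='divide'`` returns
    value/S.  S(10 deg) = 1 so a 10-degree slope leaves values unchanged in
    either mode.
    """
    s = slope_factor(theta)
    if mode == "multiply":
        return value * s
    if mode == "divide":
        if s == 0:
            raise ZeroDivisionError("slope factor is 0; cannot divide")
        return value / s
    raise ValueError(f"unknown correction mode {mode!r}")


def seasonal_aggregate(fluxes: pd.DataFrame) -> pd.DataFrame:
    """Per-season, per-richness flux means and standard errors.

    ``fluxes`` needs columns ``date`` (datetime-like), ``flux`` and
    ``richness``.  Growing season is April-October, non-growing
    November-March.  Season/richness combinations with no data are reported
    with NaN mean/SE, never as zero.
    """
    required = {"date", "flux", "richness"}
    missing = required - set(fluxes.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = fluxes.copy()
    months = pd.to_datetime(df["date"]).dt.month
    df["season"] = np.where(
        months.isin(list(GROWING_MONTHS)), "growing", "non_growing"
    )
    grouped = (
        df.groupby(["season", "richness"])["flux"]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="size")
        .reset_index()
    )
    # report missing season/richness combinations explicitly
    full = pd.MultiIndex.from_product(
        [["growing", "non_growing"], sorted(df["richness"].unique())],
        names=["season", "richness"],
    )
    grouped = (
        grouped.set_index(["season", "richness"]).reindex(full).reset_index()
    )
    grouped["n"] = grouped["n"].fillna(0).astype(int)
    return grouped


def diversity_level_test(fluxes_by_group: dict[int, Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and p-value across richness groups."""
    if len(fluxes_by_group) < 2:
        raise ValueError("need >= 2 richness groups")
    groups = []
    for richness, vals in fluxes_by_group.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {richness} has < 2 values")
        groups.append(arr)
    flat = np.concatenate(groups)
    if np.all(flat == flat[0]):
        # All observations identical: no evidence of differences.
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
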