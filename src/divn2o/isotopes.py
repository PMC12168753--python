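"""N2O isotopocule source partitioning in the SP/delta18O plane.

The linear N2O molecule carries nitrogen isotope information at two
positions: the central (alpha) and terminal (beta) atoms.  Their
difference, the site preference

    SP = delta15N_alpha - delta15N_beta            (per mil)

is a pathway diagnostic that is independent of the substrate isotopic
composition: nitrification (hydroxylamine oxidation) produces N2O with
high SP (~+33 per mil) while bacterial denitrification produces SP near 0.
Combined with delta18O of N2O, a measured sample is modelled as a
two-endmember production mixture displaced along a Rayleigh reduction
vector (partial N2O -> N2 consumption by denitrifiers enriches the
residual N2O in both SP and 18O):

    delta_meas = delta_mix(f_bD) + eps * ln(1 - reduced_fraction)

applied on both the SP and delta18O axes with pathway-specific epsilon.
Because ln(1 - reduced_fraction) must agree between the two axes, the
bacterial-denitrification production share f_bD has a closed form and the
reduced fraction follows from the SP displacement.  This is the "SP/O MAP"
construction of the N2O isotope literature.

Endmember means, ranges and Rayleigh enrichment factors are inputs loaded
from a YAML config (``divn2o/data/endmembers.yaml`` ships literature-typical
defaults, intended to be replaced with site-specific values).  The
delta18O endmembers can be adjusted for the local soil-water delta18O,
since the oxygen in microbially produced N2O largely exchanges with water;
SP endmembers are never adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "IsotopeSample",
    "EndmemberSet",
    "SourcePartition",
    "site_preference",
    "bulk_delta",
    "build_endmembers",
    "load_endmember_config",
    "default_endmembers",
    "spo_map_partition",
    "monte_carlo_partition",
]


def site_preference(delta_alpha: float, delta_beta: float):
    """Site preference SP = delta15N_alpha - delta15N_beta (per mil)."""
    return np.asarray(delta_alpha) - np.asarray(delta_beta)


def bulk_delta(delta_alpha: float, delta_beta: float):
    """Bulk delta15N = (delta15N_alpha + delta15N_beta) / 2 (per mil)."""
    return (np.asarray(delta_alpha) + np.asarray(delta_beta)) / 2.0


@dataclass
class IsotopeSample:
    """One N2O isotopocule measurement (per mil; N vs AIR, O vs VSMOW)."""

    delta15N_alpha: float
    delta15N_beta: float
    delta18O: float
    soil_water_d18O: float | None = None
    plot_id: str = ""
    richness: int | None = None
    date: object = None

    def __post_init__(self) -> None:
        for name in ("delta15N_alpha", "delta15N_beta", "delta18O"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    @property
    def sp(self) -> float:
        return float(site_preference(self.delta15N_alpha, self.delta15N_beta))

    @property
    def bulk(self) -> float:
        return float(bulk_delta(self.delta15N_alpha, self.delta15N_beta))


@dataclass
class EndmemberSet:
    """Production endmembers and Rayleigh reduction enrichment factors.

    All values per mil.  ``*_range`` are (low, high) intervals that must
    contain the corresponding mean; they drive the Monte-Carlo propagation.
    Enrichment factors are negative under the residual-enrichment
    convention used here (delta_residual = delta0 + eps*ln r with r the
    unreduced fraction, ln r < 0, so negative eps enriches the residual).
    """

    sp_nitrification: float
    sp_bacterial_denitrification: float
    d18o_nitrification: float
    d18o_bacterial_denitrification: float
    eps_sp_reduction: float
    eps_18o_reduction: float
    sp_nitrification_range: tuple[float, float] | None = None
    sp_bacterial_denitrification_range: tuple[float, float] | None = None
    d18o_nitrification_range: tuple[float, float] | None = None
    d18o_bacterial_denitrification_range: tuple[float, float] | None = None
    eps_sp_reduction_range: tuple[float, float] | None = None
    eps_18o_reduction_range: tuple[float, float] | None = None
    d18o_water_reference: float = 0.0
    d18o_water_coupling: float = 1.0

    _MEANS = (
        "sp_nitrification",
        "sp_bacterial_denitrification",
        "d18o_nitrification",
        "d18o_bacterial_denitrification",
        "eps_sp_reduction",
        "eps_18o_reduction",
    )

    def __post_init__(self) -> None:
        if self.eps_sp_reduction == 0 or self.eps_18o_reduction == 0:
            raise ValueError("Rayleigh enrichment factors must be nonzero")
        for name in self._MEANS:
            rng = getattr(self, name + "_range")
            if rng is None:
                continue
            lo, hi = rng
            if lo > hi:
                raise ValueError(f"{name}_range is not ordered: {rng}")
            if not (lo <= getattr(self, name) <= hi):
                raise ValueError(
                    f"{name}_range {rng} does not contain mean {getattr(self, name)}"
                )


@dataclass
class SourcePartition:
    """Inferred production shares and reduction for one sample.

    ``f_nitrification + f_bacterial_denitrification = 1`` (shares of gross
    N2O production); ``reduced_fraction`` is the fraction of produced N2O
    consumed by reduction to N2 before emission.  ``feasible`` is False
    when the algebraic solution falls outside those ranges; the raw values
    are still reported (never silently clipped).
    """

    f_nitrification: float
    f_bacterial_denitrification: float
    reduced_fraction: float
    feasible: bool = True
    uncertainty: dict[str, float] | None = None
    feasible_fraction: float | None = None
    n_draws: int | None = None


def load_endmember_config(path) -> EndmemberSet:
    """Read an endmember YAML config file into an :class:`EndmemberSet`."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _endmembers_from_dict(cfg)


def _endmembers_from_dict(cfg: dict) -> EndmemberSet:
    kwargs = {}
    for name in EndmemberSet._MEANS:
        if name not in cfg:
            raise ValueError(f"endmember config missing field: {name}")
        entry = cfg[name]
        if isinstance(entry, dict):
            kwargs[name] = float(entry["mean"])
            if "range" in entry:
                lo, hi = entry["range"]
                kwargs[name + "_range"] = (float(lo), float(hi))
        else:
            kwargs[name] = float(entry)
    kwargs["d18o_water_reference"] = float(cfg.get("d18o_water_reference", 0.0))
    kwargs["d18o_water_coupling"] = float(cfg.get("d18o_water_coupling", 1.0))
    return EndmemberSet(**kwargs)


def default_endmembers() -> EndmemberSet:
    """Packaged literature-typical endmembers (replace with site values)."""
    ref = resources.files("divn2o").joinpath("data/endmembers.yaml")
    with resources.as_file(ref) as path:
        return load_endmember_config(path)


def build_endmembers(
    config: EndmemberSet, soil_water_d18O: float | None = None
) -> EndmemberSet:
    """Adjust delta18O endmembers for the local soil-water delta18O.

    The delta18O endmembers (means and ranges) are shifted by
    ``coupling * (soil_water_d18O - d18o_water_reference)``; SP endmembers
    and enrichment factors are untouched.  With ``soil_water_d18O`` equal
    to the reference (or None) the set is returned unchanged.
    """
    if soil_water_d18O is None:
        return config
    shift = config.d18o_water_coupling * (
        soil_water_d18O - config.d18o_water_reference
    )
    if shift == 0:
        return config

    def _shift_range(rng):
        return None if rng is None else (rng[0] + shift, rng[1] + shift)

    return replace(
        config,
        d18o_nitrification=config.d18o_nitrification + shift,
        d18o_bacterial_denitrification=config.d18o_bacterial_denitrification + shift,
        d18o_nitrification_range=_shift_range(config.d18o_nitrification_range),
        d18o_bacterial_denitrification_range=_shift_range(
            config.d18o_bacterial_denitrification_range
        ),
        d18o_water_reference=soil_water_d18O,
    )


def _solve(sp_m, o_m, em: EndmemberSet):
    """Closed-form (f_bD, reduced_fraction); raises on degenerate geometry."""
    sp_ni, sp_bd = em.sp_nitrification, em.sp_bacterial_denitrification
    o_ni, o_bd = em.d18o_nitrification, em.d18o_bacterial_denitrification
    eps_sp, eps_o = em.eps_sp_reduction, em.eps_18o_reduction
    d_sp, d_o = sp_bd - sp_ni, o_bd - o_ni
    denom = d_o * eps_sp - d_sp * eps_o
    scale = max(
        abs(d_o * eps_sp), abs(d_sp * eps_o), abs(eps_sp), abs(eps_o), 1.0
    )
    if abs(denom) < 1e-12 * scale:
        raise ValueError(
            "degenerate geometry: mixing line parallel to reduction vector"
        )
    f_bd = ((o_m - o_ni) * eps_sp - (sp_m - sp_ni) * eps_o) / denom
    sp_mix = sp_ni + f_bd * d_sp
    ln_r = (sp_m - sp_mix) / eps_sp
    reduced = 1.0 - math.exp(ln_r)
    return f_bd, reduced


def spo_map_partition(sample: IsotopeSample, endmembers: EndmemberSet) -> SourcePartition:
    """Invert one sample to (f_Ni, f_bD, reduced_fraction).

    Solves the two-equation mixing-plus-Rayleigh system described in the
    module docstring.  If the sample carries ``soil_water_d18O`` the
    endmembers are water-adjusted first.  Solutions with f_bD outside
    [0, 1] or reduced_fraction outside [0, 1) are returned with
    ``feasible=False`` and left unclipped.
    """
    em = build_endmembers(endmembers, sample.soil_water_d18O)
    f_bd, reduced = _solve(sample.sp, sample.delta18O, em)
    feasible = (0.0 <= f_bd <= 1.0) and (0.0 <= reduced < 1.0)
    return SourcePartition(
        f_nitrification=1.0 - f_bd,
        f_bacterial_denitrification=f_bd,
        reduced_fraction=reduced,
        feasible=feasible,
    )


def monte_carlo_partition(
    sample: IsotopeSample,
    endmembers: EndmemberSet,
    n_draws: int = 10_000,
    seed: int | None = None,
) -> SourcePartition:
    """Propagate endmember ranges through the inversion by uniform sampling.

    Each draw replaces every endmember mean that has a declared range with
    a uniform draw over that range (zero-width/absent ranges stay at the
    mean, so the result then equals the deterministic solution with SD 0).
    Infeasible draws are discarded; means/SDs are over feasible draws and
    the feasible fraction is reported.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    em = build_endmembers(endmembers, sample.soil_water_d18O)
    rng = np.random.default_rng(seed)

    def draws(name):
        rng_range = getattr(em, name + "_range")
        mean = getattr(em, name)
        if rng_range is None or rng_range[0] == rng_range[1]:
            return np.full(n_draws, mean)
        return rng.uniform(rng_range[0], rng_range[1], n_draws)

    sp_ni = draws("sp_nitrification")
    sp_bd = draws("sp_bacterial_denitrification")
    o_ni = draws("d18o_nitrification")
    o_bd = draws("d18o_bacterial_denitrification")
    eps_sp = draws("eps_sp_reduction")
    eps_o = draws("eps_18o_reduction")

    d_sp, d_o = sp_bd - sp_ni, o_bd - o_ni
    denom = d_o * eps_sp - d_sp * eps_o
    ok = np.abs(denom) > 1e-12
    f_bd = np.full(n_draws, np.nan)
    f_bd[ok] = (
        (sample.delta18O - o_ni[ok]) * eps_sp[ok]
        - (sample.sp - sp_ni[ok]) * eps_o[ok]
    ) / denom[ok]
    sp_mix = sp_ni + f_bd * d_sp
    with np.errstate(invalid="ignore", over="ignore"):
        reduced = 1.0 - np.exp((sample.sp - sp_mix) / eps_sp)
    feas = ok & (f_bd >= 0) & (f_bd <= 1) & (reduced >= 0) & (reduced < 1)
    n_feas = int(feas.sum())
    if n_feas == 0:
        det = _solve(sample.sp, sample.delta18O, em)
        raise ValueError(
            "no feasible Monte-Carlo draws; deterministic solution is "
            f"f_bD={det[0]:.3f}, reduced_fraction={det[1]:.3f} — sample lies "
            "outside the endmember mixing/reduction region"
        )
    fb, rd = f_bd[feas], reduced[feas]
    return SourcePartition(
        f_nitrification=float(1.0 - fb.mean()),
        f_bacterial_denitrification=float(fb.mean()),
        reduced_fraction=float(rd.mean()),
        feasible=True,
        uncertainty={
            "f_bacterial_denitrification": float(fb.std(ddof=1)) if n_feas > 1 else 0.0,
            "f_nitrification": float(fb.std(ddof=1)) if n_feas > 1 else 0.0,
            "reduced_fraction": float(rd.std(ddof=1)) if n_feas > 1 else 0.0,
        },
        feasible_fraction=n_feas / n_draws,
        n_draws=n_draws,
    )
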