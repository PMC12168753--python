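"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the shape of one class of real inputs — paired
meta-analysis observations whose effect size declines linearly in
log2(richness), linear-in-time chamber concentration series, isotope
triplets from two-endmember mixing plus Rayleigh reduction, smooth
seasonal site forcing, coarse gridded monthly forcing with a forest mask,
and process-model flux observations — so all downstream analyses can be
tested end-to-end without external data downloads.  All generators are
pure functions of their spec and seed; noiseless outputs invert exactly
under the corresponding analysis operations.

The generators do not attempt to mimic the spatial covariance of real
climatology products; seasonality is a single annual sinusoid per
variable, with staggered phases so that drivers are not collinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .chamber import ChamberSeries, n2o_density, _PPB_MIN_TO_UG_FACTOR
from .gridsim import (
    GridForcing,
    ZONE_TEMPERATE_BOREAL,
    ZONE_TROPICAL_SUBTROPICAL,
)
from .isotopes import EndmemberSet, IsotopeSample, build_endmembers
from .micn import DiversityFactor, MicNParams, SiteForcing, simulate_site

__all__ = [
    "SynthMetaSpec",
    "SynthGridSpec",
    "DEFAULT_FORCING_RANGES",
    "gen_meta_dataset",
    "gen_chamber_series",
    "gen_isotope_samples",
    "gen_site_forcing",
    "gen_grid_forcing",
    "gen_model_observations",
]

#: Tree-diversity levels of the in-situ experiment the generators emulate.
DEFAULT_RICHNESS_LEVELS = (1, 2, 4, 8, 16, 24)

_BIOMES = ("boreal", "temperate", "subtropical", "tropical")


@dataclass
class SynthMetaSpec:
    """Conditions for the synthetic paired-observation (meta-analysis) set.

    The underlying true effect size at treatment richness r is
    ``true_intercept + true_slope * log2(r)`` plus Gaussian between-study
    heterogeneity; within-study sampling noise comes from drawing the
    stated number of plot replicates.
    """

    n_studies: int = 201
    richness_levels: tuple = DEFAULT_RICHNESS_LEVELS
    true_slope: float = -0.3
    true_intercept: float = 0.0
    between_study_sd: float = 0.15
    reps_range: tuple[int, int] = (3, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if any(r < 1 for r in self.richness_levels):
            raise ValueError("richness_levels must all be >= 1")
        if not any(r >= 2 for r in self.richness_levels):
            raise ValueError("richness_levels needs at least one level >= 2")
        if self.between_study_sd < 0:
            raise ValueError("between_study_sd must be >= 0")
        lo, hi = self.reps_range
        if lo < 2 or hi < lo:
            raise ValueError("reps_range must be an ordered pair with min >= 2")


@dataclass
class SynthGridSpec:
    """Conditions for the synthetic global forcing grid.

    The grid tiles the globe (cell size 180/n_lat degrees of latitude);
    pick n_lon = 2*n_lat for square cells.  ``field_ranges`` bounds each
    variable; None uses :data:`DEFAULT_FORCING_RANGES`.
    """

    n_lat: int = 10
    n_lon: int = 20
    n_months: int = 12
    forest_fraction: float = 0.3
    zone_boundary_deg: float = 30.0
    field_ranges: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")
        if not 0.0 <= self.forest_fraction <= 1.0:
            raise ValueError("forest_fraction must be in [0, 1]")
        ranges = self.field_ranges or DEFAULT_FORCING_RANGES
        for name, (lo, hi) in ranges.items():
            if lo > hi:
                raise ValueError(f"range for {name} not ordered: ({lo}, {hi})")
        lo, hi = ranges.get("moisture", (0.0, 1.0))
        if lo < 0 or hi > 1:
            raise ValueError("moisture range must lie in [0, 1]")


#: Plausible ranges for an acidic subtropical forest site (units as in
#: :class:`~divn2o.micn.SiteForcing`; supplies in g N m-2 month-1).
DEFAULT_FORCING_RANGES = {
    "temperature": (8.0, 28.0),
    "moisture": (0.38, 0.82),
    "ph": (4.5, 5.6),
    "organic_c": (2600.0, 3400.0),
    "nh4_supply": (0.15, 0.8),
    "no3_supply": (0.08, 0.6),
}

# Peak month index (0 = January) per variable; staggered on purpose so the
# seasonal drivers are linearly independent.
_FORCING_PHASES = {
    "temperature": 6,
    "moisture": 8,
    "ph": 2,
    "organic_c": 10,
    "nh4_supply": 4,
    "no3_supply": 9,
}


def gen_meta_dataset(spec: SynthMetaSpec) -> pd.DataFrame:
    """Synthetic paired control/treatment observation table.

    Control plots are single-species forests; each study's treatment
    richness cycles through the spec's levels (>= 2).  Group means and SDs
    are empirical moments of simulated plot replicates, so with large
    replicate counts and zero between-study SD the empirical SMDs converge
    to the true effect-size line.
    """
    rng = np.random.default_rng(spec.seed)
    levels = [r for r in spec.richness_levels if r >= 2]
    lo, hi = spec.reps_range
    rows = []
    for i in range(spec.n_studies):
        richness = levels[i % len(levels)]
        true_smd = (
            spec.true_intercept
            + spec.true_slope * np.log2(richness)
            + (rng.normal(0.0, spec.between_study_sd) if spec.between_study_sd > 0 else 0.0)
        )
        mean_c = rng.lognormal(np.log(8.0), 0.6)  # ug m-2 h-1
        sigma = 0.35 * mean_c  # common within-group SD
        mean_t = mean_c + true_smd * sigma
        n_c = int(rng.integers(lo, hi + 1))
        n_t = int(rng.integers(lo, hi + 1))
        reps_c = rng.normal(mean_c, sigma, n_c)
        reps_t = rng.normal(mean_t, sigma, n_t)
        rows.append(
            {
                "study_id": f"S{i:04d}",
                "richness": richness,
                "mean_control": reps_c.mean(),
                "sd_control": reps_c.std(ddof=1),
                "n_control": n_c,
                "mean_treatment": reps_t.mean(),
                "sd_treatment": reps_t.std(ddof=1),
                "n_treatment": n_t,
                "biome": _BIOMES[int(rng.integers(len(_BIOMES)))],
                "latitude": float(rng.uniform(-55, 65)),
                "longitude": float(rng.uniform(-180, 180)),
                "true_smd": true_smd,
            }
        )
    return pd.DataFrame(rows)


def gen_chamber_series(
    true_flux: float,
    height: float = 0.3,
    temperature: float = 25.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    times=(0.0, 10.0, 20.0, 30.0, 40.0),
    ambient_ppb: float = 330.0,
    **series_kwargs,
) -> ChamberSeries:
    """Chamber series whose noiseless slope inverts to ``true_flux`` exactly.

    The concentration slope is the flux equation solved for dC/dt; Gaussian
    noise (``noise_sd`` ppb) is added per time point when requested.
    """
    if height <= 0:
        raise ValueError("chamber height must be positive")
    rho = n2o_density(temperature)
    slope = true_flux / (rho * height * _PPB_MIN_TO_UG_FACTOR)  # ppb min-1
    t = np.asarray(times, dtype=float)
    conc = ambient_ppb + slope * t
    if noise_sd > 0:
        conc = conc + np.random.default_rng(seed).normal(0.0, noise_sd, t.size)
    return ChamberSeries(
        times=t,
        concentrations=conc,
        chamber_height=height,
        air_temperature=temperature,
        **series_kwargs,
    )


def gen_isotope_samples(
    f_bD: float,
    reduced_fraction: float,
    endmembers: EndmemberSet,
    noise_sd: float = 0.0,
    n: int = 1,
    seed: int | None = None,
    soil_water_d18O: float | None = None,
    bulk_d15n: float = -15.0,
) -> list[IsotopeSample]:
    """Forward SP/O MAP samples: endmember mixing plus Rayleigh reduction.

    The production mixture (share ``f_bD`` bacterial denitrification,
    ``1-f_bD`` nitrification) is displaced along the reduction vector by
    ``eps * ln(1 - reduced_fraction)`` on both axes; the bulk delta15N is a
    free bookkeeping value used only to split SP into alpha/beta.  Noise
    (per mil) is added independently to delta15N_alpha, delta15N_beta and
    delta18O.  Noiseless samples invert exactly under
    :func:`~divn2o.isotopes.spo_map_partition`.
    """
    if not 0.0 <= f_bD <= 1.0:
        raise ValueError("f_bD must be in [0, 1]")
    if not 0.0 <= reduced_fraction < 1.0:
        raise ValueError("reduced_fraction must be in [0, 1)")
    em = build_endmembers(endmembers, soil_water_d18O)
    sp_mix = f_bD * em.sp_bacterial_denitrification + (1 - f_bD) * em.sp_nitrification
    o_mix = (
        f_bD * em.d18o_bacterial_denitrification + (1 - f_bD) * em.d18o_nitrification
    )
    ln_r = np.log(1.0 - reduced_fraction)
    sp = sp_mix + em.eps_sp_reduction * ln_r
    o = o_mix + em.eps_18o_reduction * ln_r
    rng = np.random.default_rng(seed)
    samples = []
    for _ in range(n):
        alpha = bulk_d15n + sp / 2.0
        beta = bulk_d15n - sp / 2.0
        oo = o
        if noise_sd > 0:
            alpha += rng.normal(0.0, noise_sd)
            beta += rng.normal(0.0, noise_sd)
            oo += rng.normal(0.0, noise_sd)
        samples.append(
            IsotopeSample(
                delta15N_alpha=float(alpha),
                delta15N_beta=float(beta),
                delta18O=float(oo),
                soil_water_d18O=soil_water_d18O,
            )
        )
    return samples


def _seasonal_series(rng, n_months, lo, hi, peak_month, noise_frac=0.03, lat_shift=0.0):
    span = hi - lo
    mid = (hi + lo) / 2.0 + lat_shift
    amp = 0.35 * span
    m = np.arange(n_months)
    vals = mid + amp * np.cos(2 * np.pi * (m - peak_month) / 12.0)
    if noise_frac > 0 and span > 0:
        vals = vals + rng.normal(0.0, noise_frac * span, n_months)
    return np.clip(vals, lo, hi)


def gen_site_forcing(
    n_months: int = 36,
    seed: int = 0,
    ranges: dict | None = None,
) -> SiteForcing:
    """Smooth seasonal monthly forcing for one site.

    Each variable follows one annual sinusoid (variable-specific peak
    month) plus small Gaussian noise, clipped into its declared range;
    degenerate (min == max) ranges give constant series.
    """
    if n_months < 1:
        raise ValueError("n_months must be >= 1")
    ranges = dict(DEFAULT_FORCING_RANGES, **(ranges or {}))
    rng = np.random.default_rng(seed)
    data = {}
    for var in SiteForcing.FIELDS:
        lo, hi = ranges[var]
        data[var] = _seasonal_series(rng, n_months, lo, hi, _FORCING_PHASES[var])
    return SiteForcing(**data)


def gen_grid_forcing(spec: SynthGridSpec) -> GridForcing:
    """Synthetic gridded monthly forcing tiling the globe.

    Temperature declines poleward and its seasonal phase flips in the
    southern hemisphere; other variables follow the site-forcing sinusoids.
    The forest mask is Bernoulli(``forest_fraction``) per cell and the
    climate zone is tropical/subtropical where |lat| <= zone boundary.
    """
    rng = np.random.default_rng(spec.seed)
    ranges = dict(DEFAULT_FORCING_RANGES, **(spec.field_ranges or {}))
    res_lat = 180.0 / spec.n_lat
    res_lon = 360.0 / spec.n_lon
    lat = -90.0 + res_lat * (np.arange(spec.n_lat) + 0.5)
    lon = -180.0 + res_lon * (np.arange(spec.n_lon) + 0.5)
    shape = (spec.n_months, spec.n_lat, spec.n_lon)
    fields = {v: np.empty(shape) for v in SiteForcing.FIELDS}
    t_lo, t_hi = ranges["temperature"]
    for i, phi in enumerate(lat):
        phase_shift = 0 if phi >= 0 else 6
        # poleward cooling: shift the temperature midpoint down within range
        lat_shift = -0.5 * (t_hi - t_lo) * abs(phi) / 90.0
        for j in range(spec.n_lon):
            for var in SiteForcing.FIELDS:
                lo, hi = ranges[var]
                peak = (_FORCING_PHASES[var] + phase_shift) % 12
                shift = lat_shift if var == "temperature" else 0.0
                fields[var][:, i, j] = _seasonal_series(
                    rng, spec.n_months, lo, hi, peak, lat_shift=shift
                )
    forest = rng.random((spec.n_lat, spec.n_lon)) < spec.forest_fraction
    zone = np.where(
        np.abs(lat)[:, None] <= spec.zone_boundary_deg,
        ZONE_TROPICAL_SUBTROPICAL,
        ZONE_TEMPERATE_BOREAL,
    ) * np.ones((1, spec.n_lon), dtype=int)
    ds = xr.Dataset(
        {
            "soil_temperature": (("time", "lat", "lon"), fields["temperature"]),
            "soil_moisture": (("time", "lat", "lon"), fields["moisture"]),
            "ph": (("time", "lat", "lon"), fields["ph"]),
            "organic_c": (("time", "lat", "lon"), fields["organic_c"]),
            "nh4_supply": (("time", "lat", "lon"), fields["nh4_supply"]),
            "no3_supply": (("time", "lat", "lon"), fields["no3_supply"]),
            "forest_mask": (("lat", "lon"), forest),
            "zone": (("lat", "lon"), zone),
        },
        coords={"time": np.arange(spec.n_months), "lat": lat, "lon": lon},
    )
    return GridForcing(ds)


def gen_model_observations(
    params: MicNParams,
    fpd: DiversityFactor,
    forcing: SiteForcing,
    richness_levels=DEFAULT_RICHNESS_LEVELS,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Monthly process-model fluxes per richness, optionally noisy.

    Ground truth for calibration tests: with ``noise_sd=0`` the ``flux``
    column equals :func:`~divn2o.micn.simulate_site` output exactly
    (g N m-2 month-1, default initial pools, no spin-up).
    """
    params.validate()
    rng = np.random.default_rng(seed)
    frames = []
    for r in richness_levels:
        flux = simulate_site(forcing, params, richness=r, fpd=fpd)
        if noise_sd > 0:
            flux = flux + rng.normal(0.0, noise_sd, flux.size)
        frames.append(
            pd.DataFrame(
                {"richness": r, "month": np.arange(forcing.n_months), "flux": flux}
            )
        )
    return pd.concat(frames, ignore_index=True)
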