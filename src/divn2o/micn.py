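"""Microbial nitrogen-cycle N2O model with a tree-diversity scaling (MicN-SR).

The model tracks monthly soil mineral-nitrogen pools (NH4+, an internal
nitrite/NOx pool, NO3-, and a transient N2O pool, all g N m-2) and four
microbial N2O production/consumption pathways:

* autotrophic nitrification — ammonia oxidation by archaea (AOA) and
  bacteria (AOB) to nitrite, completed to nitrate by nitrite oxidizers
  (NOB); a small yield of the oxidized N escapes as N2O,
* heterotrophic nitrification — organic-carbon co-limited oxidation of
  NH4+ straight to NO3-,
* nitrifier denitrification — reduction of nitrite by AOB to N2O/N2,
* denitrifier denitrification — reduction of NO3- by heterotrophic
  denitrifiers, partitioned between N2O and N2 by a yield, plus
  consumption of N2O itself (reduction to N2).

Every pathway follows Michaelis-Menten substrate limitation times
environmental scalars (Q10 temperature response; a nitrification moisture
optimum vs a monotone denitrification moisture response; Gaussian pH
responses, with separate optima and NH4+ half-saturations for AOA and AOB
— AOA dominate acidic, ammonium-poor soils).  Each of the six maximum
oxidation/reduction rates (K_max) is multiplied by a tree-diversity factor
F_PD(richness), a per-pathway power law anchored at F_PD(1) = 1: this is
the species-richness extension that turns the base microbial N model into
its diversity-aware variant.

Monthly NH4+/NO3- forcing values are interpreted as substrate *supplies*
(g N m-2 month-1) added to the pools; the nitrogen budget
(pool change + N2O emission + N2 loss = supply) closes to machine
precision each step.  Integration is explicit Euler at monthly resolution
with proportional substrate-capping guards so pools can never go negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "KMAX_NAMES",
    "MicNParams",
    "HalfSaturation",
    "N2OYields",
    "EnvParams",
    "SoilState",
    "SiteForcing",
    "DiversityFactor",
    "ProcessRates",
    "env_scalars",
    "diversity_factor",
    "process_rates",
    "step_month",
    "simulate_site",
    "fit_diversity_factor",
    "load_params",
    "save_params",
    "default_params",
    "flux_to_ug_m2_h",
    "HOURS_PER_MONTH",
]

#: Calibratable maximum oxidation/reduction rates, in model order.
KMAX_NAMES = (
    "kmax_nitr_aoa",
    "kmax_nitr_aob",
    "kmax_nitr_nob",
    "kmax_nitrh",
    "kmax_nox_denitr",
    "kmax_nox_aob",
)

HOURS_PER_MONTH = 365.25 * 24.0 / 12.0  # 730.5


def flux_to_ug_m2_h(flux_g_m2_month):
    """Convert a monthly areal flux (g N m-2 month-1) to ug N m-2 h-1."""
    return np.asarray(flux_g_m2_month) * 1e6 / HOURS_PER_MONTH


@dataclass
class HalfSaturation:
    """Michaelis-Menten half-saturation constants (substrate units)."""

    nh4_aoa: float = 0.3  # g N m-2; AOA have high ammonium affinity
    nh4_aob: float = 1.2  # g N m-2; AOB saturate only at high NH4+
    nh4_h: float = 1.0  # g N m-2, heterotrophic nitrification
    nox: float = 0.25  # g N m-2, lumped nitrite/NOx pool
    no3: float = 1.5  # g N m-2
    organic_c: float = 1500.0  # g C m-2 (co-limitation of heterotrophs)
    n2o: float = 0.05  # g N m-2, N2O reduction

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"half_saturation.{name} must be > 0, got {v}")


@dataclass
class N2OYields:
    """Fraction of each pathway's nitrogen throughput emitted as N2O."""

    ammonia_oxidation: float = 0.02
    heterotrophic: float = 0.05
    nitrifier_denitrification: float = 0.60
    denitrifier_denitrification: float = 0.25

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"n2o_yield.{name} must be in [0, 1], got {v}")


@dataclass
class EnvParams:
    """Environmental response parameters.

    f_T = Q10**((T - t_ref)/10) equals 1 at the reference temperature and
    exceeds 1 above it (documented headroom); moisture and pH scalars are
    bounded by 1.
    """

    t_ref: float = 15.0  # deg C
    q10: float = 2.0
    moisture_opt_nitr: float = 0.60  # water-filled pore fraction
    moisture_width_nitr: float = 0.25
    moisture_exp_denitr: float = 2.0  # f = moisture**exp, monotone
    ph_opt: float = 5.2  # generic pathways (acidic forest soils)
    ph_width: float = 1.5
    ph_opt_aoa: float = 4.7
    ph_width_aoa: float = 0.9
    ph_opt_aob: float = 5.6
    ph_width_aob: float = 0.8
    ph_opt_het: float = 4.6  # fungal heterotrophic nitrifiers, acid-tolerant
    ph_width_het: float = 1.0

    def validate(self) -> None:
        if self.q10 <= 0:
            raise ValueError("q10 must be > 0")
        for name in ("moisture_width_nitr", "ph_width", "ph_width_aoa", "ph_width_aob", "ph_width_het"):
            if getattr(self, name) <= 0:
                raise ValueError(f"env.{name} must be > 0")
        if not 0 < self.moisture_opt_nitr <= 1:
            raise ValueError("moisture_opt_nitr must be in (0, 1]")


@dataclass
class MicNParams:
    """All model parameters: six K_max, N2O reduction, kinetics and env."""

    kmax_nitr_aoa: float = 0.35  # g N m-2 month-1 (all kmax)
    kmax_nitr_aob: float = 0.25
    kmax_nitr_nob: float = 0.50
    kmax_nitrh: float = 0.30
    kmax_nox_denitr: float = 0.40
    kmax_nox_aob: float = 0.15
    kmax_n2o_reduction: float = 0.10
    uptake_nh4: float = 0.40  # plant uptake + immobilization, month-1
    uptake_no3: float = 0.25  # plant uptake + leaching, month-1
    half_saturation: HalfSaturation = field(default_factory=HalfSaturation)
    n2o_yield: N2OYields = field(default_factory=N2OYields)
    env: EnvParams = field(default_factory=EnvParams)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in KMAX_NAMES + ("kmax_n2o_reduction",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("uptake_nh4", "uptake_no3"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1) per month")
        self.half_saturation.validate()
        self.n2o_yield.validate()
        self.env.validate()

    def kmax_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in KMAX_NAMES])

    def with_kmax(self, values) -> "MicNParams":
        """New parameter set with the six K_max replaced (dict or vector)."""
        if isinstance(values, dict):
            unknown = set(values) - set(KMAX_NAMES)
            if unknown:
                raise ValueError(f"unknown K_max names: {sorted(unknown)}")
            return replace(self, **values)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(KMAX_NAMES),):
            raise ValueError(f"expected {len(KMAX_NAMES)} K_max values")
        return replace(self, **dict(zip(KMAX_NAMES, values)))


@dataclass
class SoilState:
    """Nitrogen pools (g N m-2) plus the environmental drivers of the month."""

    nh4: float = 0.5
    nox: float = 0.05  # internal nitrite pool
    no3: float = 1.0
    n2o_pool: float = 0.0  # transient; vented each month
    organic_c: float = 3000.0  # g C m-2
    temperature: float = 15.0  # deg C
    moisture: float = 0.6  # water-filled pore fraction
    ph: float = 5.0

    def validate(self) -> None:
        for name in ("nh4", "nox", "no3", "n2o_pool", "organic_c"):
            if getattr(self, name) < 0:
                raise ValueError(f"pool {name} must be >= 0")
        if not 0.0 <= self.moisture <= 1.0:
            raise ValueError("moisture must be in [0, 1]")
        if self.temperature <= -273.15:
            raise ValueError("nonphysical temperature")

    def total_n(self) -> float:
        return self.nh4 + self.nox + self.no3 + self.n2o_pool


@dataclass
class SiteForcing:
    """Monthly site drivers; NH4/NO3 are supplies in g N m-2 month-1."""

    temperature: np.ndarray
    moisture: np.ndarray
    ph: np.ndarray
    organic_c: np.ndarray
    nh4_supply: np.ndarray
    no3_supply: np.ndarray

    FIELDS = ("temperature", "moisture", "ph", "organic_c", "nh4_supply", "no3_supply")

    def __post_init__(self) -> None:
        arrays = [np.atleast_1d(np.asarray(getattr(self, f), float)) for f in self.FIELDS]
        n = arrays[0].size
        if n < 1:
            raise ValueError("forcing must cover >= 1 month")
        if any(a.size != n for a in arrays):
            raise ValueError("forcing fields must have equal length")
        for f, a in zip(self.FIELDS, arrays):
            setattr(self, f, a)

    @property
    def n_months(self) -> int:
        return self.temperature.size

    def month(self, i: int) -> dict:
        return {f: float(getattr(self, f)[i]) for f in self.FIELDS}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({f: getattr(self, f) for f in self.FIELDS})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SiteForcing":
        missing = [f for f in cls.FIELDS if f not in df.columns]
        if missing:
            raise ValueError(f"forcing table missing columns: {missing}")
        return cls(**{f: df[f].to_numpy(float) for f in cls.FIELDS})

    def repeat_years(self, n_years: int) -> "SiteForcing":
        return SiteForcing(**{f: np.tile(getattr(self, f), n_years) for f in self.FIELDS})


@dataclass
class DiversityFactor:
    """Per-pathway power-law multiplier F_PD(r) = r**b, anchored at F_PD(1)=1."""

    coefficients: dict[str, float] = field(default_factory=lambda: {n: 0.0 for n in KMAX_NAMES})
    form: str = "power_law"
    reference_richness: int = 1
    diagnostics: dict | None = None

    def __post_init__(self) -> None:
        if self.form != "power_law":
            raise ValueError(f"unknown diversity factor form {self.form!r}")
        unknown = set(self.coefficients) - set(KMAX_NAMES)
        if unknown:
            raise ValueError(f"unknown pathway names: {sorted(unknown)}")
        for n in KMAX_NAMES:
            self.coefficients.setdefault(n, 0.0)

    def multipliers(self, richness: float) -> dict[str, float]:
        if richness < 1:
            raise ValueError("richness must be >= 1")
        return {n: float(richness) ** b for n, b in self.coefficients.items()}


@dataclass
class ProcessRates:
    """Realized monthly rates (g N m-2 month-1) for one step."""

    autotrophic_nitrification: float
    heterotrophic_nitrification: float
    nitrifier_denitrification: float
    denitrifier_denitrification: float
    nitrite_oxidation: float
    n2o_production: dict[str, float]
    n2o_reduction: float
    n2_loss: float
    plant_uptake: float
    external_input: float

    @property
    def total_n2o_production(self) -> float:
        return sum(self.n2o_production.values())


def _mm(substrate: float, k_half: float) -> float:
    return 0.0 if substrate <= 0 else substrate / (substrate + k_half)


def _gauss(x: float, opt: float, width: float) -> float:
    return float(np.exp(-0.5 * ((x - opt) / width) ** 2))


def env_scalars(state: SoilState, params: MicNParams) -> dict[str, float]:
    """Temperature, moisture and pH response scalars for the current state.

    Returns f_T (Q10, unbounded above), f_W_nitr (Gaussian around the
    nitrification moisture optimum), f_W_denitr (monotone power of
    moisture), and Gaussian f_pH variants (generic, AOA, AOB).
    """
    env = params.env
    f_t = env.q10 ** ((state.temperature - env.t_ref) / 10.0)
    f_w_nitr = _gauss(state.moisture, env.moisture_opt_nitr, env.moisture_width_nitr)
    f_w_denitr = float(np.clip(state.moisture, 0.0, 1.0) ** env.moisture_exp_denitr)
    return {
        "f_T": float(f_t),
        "f_W_nitr": f_w_nitr,
        "f_W_denitr": f_w_denitr,
        "f_pH": _gauss(state.ph, env.ph_opt, env.ph_width),
        "f_pH_aoa": _gauss(state.ph, env.ph_opt_aoa, env.ph_width_aoa),
        "f_pH_aob": _gauss(state.ph, env.ph_opt_aob, env.ph_width_aob),
        "f_pH_het": _gauss(state.ph, env.ph_opt_het, env.ph_width_het),
    }


def diversity_factor(richness: float, fpd: DiversityFactor) -> dict[str, float]:
    """The six K_max multipliers at a given tree species richness."""
    return fpd.multipliers(richness)


def process_rates(
    state: SoilState,
    params: MicNParams,
    richness: float = 1.0,
    fpd: DiversityFactor | None = None,
) -> ProcessRates:
    """Potential (uncapped) pathway rates at the current state.

    Rates follow F_PD * K_max * MM(substrate) * environmental scalars;
    no substrate-availability capping is applied here (see
    :func:`step_month` for the guarded update).
    """
    state.validate()
    fpd = fpd or DiversityFactor()
    f = fpd.multipliers(richness)
    s = env_scalars(state, params)
    ks = params.half_saturation
    y = params.n2o_yield

    r_aoa = (
        f["kmax_nitr_aoa"] * params.kmax_nitr_aoa
        * _mm(state.nh4, ks.nh4_aoa) * s["f_T"] * s["f_W_nitr"] * s["f_pH_aoa"]
    )
    r_aob = (
        f["kmax_nitr_aob"] * params.kmax_nitr_aob
        * _mm(state.nh4, ks.nh4_aob) * s["f_T"] * s["f_W_nitr"] * s["f_pH_aob"]
    )
    r_h = (
        f["kmax_nitrh"] * params.kmax_nitrh
        * _mm(state.nh4, ks.nh4_h) * _mm(state.organic_c, ks.organic_c)
        * s["f_T"] * s["f_W_nitr"] * s["f_pH_het"]
    )
    r_nob = (
        f["kmax_nitr_nob"] * params.kmax_nitr_nob
        * _mm(state.nox, ks.nox) * s["f_T"] * s["f_W_nitr"] * s["f_pH"]
    )
    r_naob = (
        f["kmax_nox_aob"] * params.kmax_nox_aob
        * _mm(state.nox, ks.nox) * s["f_T"] * s["f_W_denitr"] * s["f_pH_aob"]
    )
    r_dd = (
        f["kmax_nox_denitr"] * params.kmax_nox_denitr
        * _mm(state.no3, ks.no3) * _mm(state.organic_c, ks.organic_c)
        * s["f_T"] * s["f_W_denitr"] * s["f_pH"]
    )
    r_red = (
        params.kmax_n2o_reduction
        * _mm(state.n2o_pool, ks.n2o) * s["f_T"] * s["f_W_denitr"] * s["f_pH"]
    )
    return ProcessRates(
        autotrophic_nitrification=r_aoa + r_aob,
        heterotrophic_nitrification=r_h,
        nitrifier_denitrification=r_naob,
        denitrifier_denitrification=r_dd,
        nitrite_oxidation=r_nob,
        n2o_production={
            "ammonia_oxidation": y.ammonia_oxidation * (r_aoa + r_aob),
            "heterotrophic": y.heterotrophic * r_h,
            "nitrifier_denitrification": y.nitrifier_denitrification * r_naob,
            "denitrifier_denitrification": y.denitrifier_denitrification * r_dd,
        },
        n2o_reduction=r_red,
        n2_loss=(1 - y.nitrifier_denitrification) * r_naob
        + (1 - y.denitrifier_denitrification) * r_dd
        + r_red,
        plant_uptake=params.uptake_nh4 * state.nh4 + params.uptake_no3 * state.no3,
        external_input=0.0,
    )


def _capped(demands: Sequence[float], available: float) -> list[float]:
    """Scale a set of competing demands proportionally to fit availability."""
    total = sum(demands)
    if total <= available or total == 0:
        return list(demands)
    scale = available / total
    return [d * scale for d in demands]


def step_month(
    state: SoilState,
    params: MicNParams,
    richness: float,
    fpd: DiversityFactor | None,
    forcing_month: dict,
) -> tuple[SoilState, float, ProcessRates]:
    """Advance the model one month.

    Supplies are added to the pools, pathway rates are computed from the
    resulting availability (explicit Euler) with proportional capping so
    no pool is overdrawn, and the month's net N2O (production minus
    reduction, plus any carried pool) is emitted.

    Returns ``(new_state, n2o_flux, rates)`` with the flux in
    g N m-2 month-1.  The nitrogen budget closes exactly:
    ``delta(pools) + flux + rates.n2_loss == rates.external_input``.
    """
    state.validate()
    fpd = fpd or DiversityFactor()
    f = fpd.multipliers(richness)
    nh4_supply = float(forcing_month["nh4_supply"])
    no3_supply = float(forcing_month["no3_supply"])
    if nh4_supply < 0 or no3_supply < 0:
        raise ValueError("substrate supplies must be >= 0")

    env_state = replace(
        state,
        temperature=float(forcing_month["temperature"]),
        moisture=float(forcing_month["moisture"]),
        ph=float(forcing_month["ph"]),
        organic_c=float(forcing_month["organic_c"]),
    )
    env_state.validate()
    s = env_scalars(env_state, params)
    ks = params.half_saturation
    y = params.n2o_yield

    nh4_avail = env_state.nh4 + nh4_supply
    common_nitr = s["f_T"] * s["f_W_nitr"]
    r_aoa = (f["kmax_nitr_aoa"] * params.kmax_nitr_aoa
             * _mm(nh4_avail, ks.nh4_aoa) * common_nitr * s["f_pH_aoa"])
    r_aob = (f["kmax_nitr_aob"] * params.kmax_nitr_aob
             * _mm(nh4_avail, ks.nh4_aob) * common_nitr * s["f_pH_aob"])
    r_h = (f["kmax_nitrh"] * params.kmax_nitrh
           * _mm(nh4_avail, ks.nh4_h) * _mm(env_state.organic_c, ks.organic_c)
           * common_nitr * s["f_pH_het"])
    u_nh4 = params.uptake_nh4 * nh4_avail
    r_aoa, r_aob, r_h, u_nh4 = _capped([r_aoa, r_aob, r_h, u_nh4], nh4_avail)

    ammonia_ox = r_aoa + r_aob
    n2o_from_amo = y.ammonia_oxidation * ammonia_ox
    nox_avail = env_state.nox + (ammonia_ox - n2o_from_amo)
    r_nob = (f["kmax_nitr_nob"] * params.kmax_nitr_nob
             * _mm(nox_avail, ks.nox) * common_nitr * s["f_pH"])
    r_naob = (f["kmax_nox_aob"] * params.kmax_nox_aob
              * _mm(nox_avail, ks.nox) * s["f_T"] * s["f_W_denitr"] * s["f_pH_aob"])
    r_nob, r_naob = _capped([r_nob, r_naob], nox_avail)

    no3_avail = env_state.no3 + no3_supply + r_nob + (1 - y.heterotrophic) * r_h
    r_dd = (f["kmax_nox_denitr"] * params.kmax_nox_denitr
            * _mm(no3_avail, ks.no3) * _mm(env_state.organic_c, ks.organic_c)
            * s["f_T"] * s["f_W_denitr"] * s["f_pH"])
    u_no3 = params.uptake_no3 * no3_avail
    r_dd, u_no3 = _capped([r_dd, u_no3], no3_avail)

    n2o_produced = (
        n2o_from_amo
        + y.heterotrophic * r_h
        + y.nitrifier_denitrification * r_naob
        + y.denitrifier_denitrification * r_dd
    )
    n2o_avail = env_state.n2o_pool + n2o_produced
    r_red = (params.kmax_n2o_reduction
             * _mm(n2o_avail, ks.n2o) * s["f_T"] * s["f_W_denitr"] * s["f_pH"])
    (r_red,) = _capped([r_red], n2o_avail)
    flux = n2o_avail - r_red

    new_state = replace(
        env_state,
        nh4=nh4_avail - (r_aoa + r_aob + r_h) - u_nh4,
        nox=nox_avail - r_nob - r_naob,
        no3=no3_avail - r_dd - u_no3,
        n2o_pool=0.0,
    )
    if min(new_state.nh4, new_state.nox, new_state.no3) < -1e-12:
        raise RuntimeError("internal error: negative pool after guarded update")
    new_state.nh4 = max(new_state.nh4, 0.0)
    new_state.nox = max(new_state.nox, 0.0)
    new_state.no3 = max(new_state.no3, 0.0)

    rates = ProcessRates(
        autotrophic_nitrification=ammonia_ox,
        heterotrophic_nitrification=r_h,
        nitrifier_denitrification=r_naob,
        denitrifier_denitrification=r_dd,
        nitrite_oxidation=r_nob,
        n2o_production={
            "ammonia_oxidation": n2o_from_amo,
            "heterotrophic": y.heterotrophic * r_h,
            "nitrifier_denitrification": y.nitrifier_denitrification * r_naob,
            "denitrifier_denitrification": y.denitrifier_denitrification * r_dd,
        },
        n2o_reduction=r_red,
        n2_loss=(1 - y.nitrifier_denitrification) * r_naob
        + (1 - y.denitrifier_denitrification) * r_dd
        + r_red,
        plant_uptake=u_nh4 + u_no3,
        external_input=nh4_supply + no3_supply,
    )
    return new_state, float(flux), rates


def simulate_site(
    forcing: SiteForcing,
    params: MicNParams,
    richness: float = 1.0,
    fpd: DiversityFactor | None = None,
    initial_state: SoilState | None = None,
) -> np.ndarray:
    """Monthly N2O flux series (g N m-2 month-1) over the forcing period."""
    state = initial_state if initial_state is not None else SoilState()
    fluxes = np.empty(forcing.n_months)
    for i in range(forcing.n_months):
        state, fluxes[i], _ = step_month(state, params, richness, fpd, forcing.month(i))
    return fluxes


def fit_diversity_factor(per_richness_kmax: pd.DataFrame) -> DiversityFactor:
    """Fit the power-law diversity factor from per-richness K_max values.

    ``per_richness_kmax`` has a ``richness`` column and one column per
    K_max name.  For each pathway the through-origin least-squares slope of
    log2(K(r)/K(1)) on log2(r) is the power-law coefficient b (richness 1
    must be present as the baseline).  Residual diagnostics (per-pathway
    coefficient SE and residual arrays) are attached.
    """
    df = per_richness_kmax
    if "richness" not in df.columns:
        raise ValueError("table needs a 'richness' column")
    missing = [n for n in KMAX_NAMES if n not in df.columns]
    if missing:
        raise ValueError(f"table missing K_max columns: {missing}")
    if df["richness"].nunique() < 3:
        raise ValueError("need >= 3 richness levels to fit the diversity factor")
    base = df[df["richness"] == 1]
    if base.empty:
        raise ValueError("richness-1 baseline required to anchor F_PD(1)=1")
    coeffs: dict[str, float] = {}
    diag: dict[str, dict] = {}
    x_all = np.log2(df["richness"].to_numpy(float))
    for name in KMAX_NAMES:
        k1 = float(base[name].mean())
        if k1 <= 0:
            raise ValueError(f"baseline {name} must be > 0")
        with np.errstate(divide="ignore"):
            yv = np.log2(df[name].to_numpy(float) / k1)
        keep = np.isfinite(yv) & (x_all >= 0)
        x, yk = x_all[keep], yv[keep]
        sxx = float(np.sum(x * x))
        if sxx == 0:
            raise ValueError("no richness > 1 rows to fit against")
        b = float(np.sum(x * yk) / sxx)
        resid = yk - b * x
        dof = max(keep.sum() - 1, 1)
        se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
        coeffs[name] = b
        diag[name] = {"se": se, "residuals": resid}
    return DiversityFactor(coefficients=coeffs, diagnostics=diag)


# ---------------------------------------------------------------------------
# parameter file I/O


def _params_to_dict(params: MicNParams) -> dict:
    d = {n: float(getattr(params, n)) for n in KMAX_NAMES}
    d["kmax_n2o_reduction"] = float(params.kmax_n2o_reduction)
    d["uptake_nh4"] = float(params.uptake_nh4)
    d["uptake_no3"] = float(params.uptake_no3)
    d["half_saturation"] = {k: float(v) for k, v in asdict(params.half_saturation).items()}
    d["n2o_yield"] = {k: float(v) for k, v in asdict(params.n2o_yield).items()}
    d["env"] = {k: float(v) for k, v in asdict(params.env).items()}
    d["schema_version"] = 1
    return d


def save_params(params: MicNParams, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_params_to_dict(params), fh, sort_keys=False)


def _params_from_dict(d: dict) -> MicNParams:
    d = dict(d)
    d.pop("schema_version", None)
    kwargs = {}
    for name in KMAX_NAMES + ("kmax_n2o_reduction", "uptake_nh4", "uptake_no3"):
        if name in d:
            kwargs[name] = float(d.pop(name))
    if "half_saturation" in d:
        kwargs["half_saturation"] = HalfSaturation(**d.pop("half_saturation"))
    if "n2o_yield" in d:
        kwargs["n2o_yield"] = N2OYields(**d.pop("n2o_yield"))
    if "env" in d:
        kwargs["env"] = EnvParams(**d.pop("env"))
    if d:
        raise ValueError(f"unknown parameter fields: {sorted(d)}")
    return MicNParams(**kwargs)


def load_params(path) -> MicNParams:
    with open(path) as fh:
        return _params_from_dict(yaml.safe_load(fh))


def default_params() -> MicNParams:
    """Packaged default parameterization (versioned YAML)."""
    ref = resources.files("divn2o").joinpath("data/micn_params.yaml")
    with resources.as_file(ref) as path:
        return load_params(path)
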