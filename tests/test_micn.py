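"""Process model: kinetics, mass balance, diversity scaling, simulation."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import divn2o as d
from divn2o.micn import (
    KMAX_NAMES,
    DiversityFactor,
    SiteForcing,
    SoilState,
    step_month,
)


def _forcing_month(**overrides):
    base = {
        "temperature": 18.0, "moisture": 0.6, "ph": 5.0,
        "organic_c": 3000.0, "nh4_supply": 0.5, "no3_supply": 0.3,
    }
    base.update(overrides)
    return base


def _balance_residual(state, new_state, flux, rates):
    delta = new_state.total_n() - state.total_n()
    return delta + flux + rates.n2_loss + rates.plant_uptake - rates.external_input


class TestEnvScalars:
    def test_reference_temperature_is_neutral(self, default_params):
        state = SoilState(temperature=default_params.env.t_ref)
        assert d.env_scalars(state, default_params)["f_T"] == pytest.approx(1.0)

    def test_q10_doubling(self, default_params):
        state = SoilState(temperature=default_params.env.t_ref + 10)
        assert d.env_scalars(state, default_params)["f_T"] == pytest.approx(2.0)

    def test_moisture_optimum_is_unity(self, default_params):
        state = SoilState(moisture=default_params.env.moisture_opt_nitr)
        s = d.env_scalars(state, default_params)
        assert s["f_W_nitr"] == pytest.approx(1.0)

    def test_denitrification_moisture_monotone(self, default_params):
        vals = [
            d.env_scalars(SoilState(moisture=m), default_params)["f_W_denitr"]
            for m in np.linspace(0.05, 1.0, 12)
        ]
        assert np.all(np.diff(vals) > 0)


class TestDiversityFactor:
    def test_reference_richness_unity(self, true_fpd):
        assert all(v == 1.0 for v in d.diversity_factor(1, true_fpd).values())

    def test_power_law_value(self):
        fpd = DiversityFactor(coefficients={n: -0.2 for n in KMAX_NAMES})
        assert d.diversity_factor(4, fpd)["kmax_nitr_aoa"] == pytest.approx(
            4**-0.2, rel=1e-12
        )

    def test_monotone_when_coefficients_share_sign(self, uniform_fpd):
        values = [
            d.diversity_factor(r, uniform_fpd)["kmax_nox_denitr"]
            for r in [1, 2, 4, 8, 16, 24]
        ]
        assert np.all(np.diff(values) < 0)

    def test_richness_below_one_rejected(self, true_fpd):
        with pytest.raises(ValueError):
            d.diversity_factor(0.5, true_fpd)

    @given(b=st.floats(-0.5, 0.5))
    @settings(deadline=None, max_examples=30)
    def test_anchored_at_one_for_any_coefficient(self, b):
        fpd = DiversityFactor(coefficients={n: b for n in KMAX_NAMES})
        assert all(v == 1.0 for v in fpd.multipliers(1).values())


class TestProcessRates:
    def test_no_ammonium_silences_nitrification_family(self, default_params):
        state = SoilState(nh4=0.0, nox=0.0)
        rates = d.process_rates(state, default_params)
        assert rates.autotrophic_nitrification == 0.0
        assert rates.heterotrophic_nitrification == 0.0
        assert rates.nitrifier_denitrification == 0.0

    def test_no_nitrate_silences_denitrifier_denitrification(self, default_params):
        rates = d.process_rates(SoilState(no3=0.0), default_params)
        assert rates.denitrifier_denitrification == 0.0

    def test_michaelis_menten_saturation_limit(self, default_params):
        # neutralize env scalars for the denitrifier pathway, saturate substrate
        params = replace(
            default_params,
            env=replace(
                default_params.env, t_ref=18.0, moisture_exp_denitr=1e-9, ph_opt=5.0
            ),
        )
        ks = params.half_saturation
        state = SoilState(
            no3=100 * ks.no3, organic_c=100 * ks.organic_c,
            temperature=18.0, moisture=1.0, ph=5.0,
        )
        rates = d.process_rates(state, params)
        assert rates.denitrifier_denitrification == pytest.approx(
            params.kmax_nox_denitr, rel=0.03
        )

    def test_rates_monotone_in_substrate(self, default_params):
        r_low = d.process_rates(SoilState(nh4=0.2), default_params)
        r_high = d.process_rates(SoilState(nh4=2.0), default_params)
        assert r_high.autotrophic_nitrification > r_low.autotrophic_nitrification


class TestStepMonth:
    def test_mass_balance_closes(self, default_params, rng):
        for _ in range(200):
            state = SoilState(
                nh4=float(rng.uniform(0, 3)), nox=float(rng.uniform(0, 0.5)),
                no3=float(rng.uniform(0, 5)), n2o_pool=float(rng.uniform(0, 0.05)),
            )
            fm = _forcing_month(
                temperature=float(rng.uniform(0, 32)),
                moisture=float(rng.uniform(0.05, 0.95)),
                ph=float(rng.uniform(4.0, 7.0)),
                nh4_supply=float(rng.uniform(0, 1.5)),
                no3_supply=float(rng.uniform(0, 1.2)),
            )
            new_state, flux, rates = step_month(state, default_params, 1.0, None, fm)
            resid = _balance_residual(state, new_state, flux, rates)
            scale = max(1.0, state.total_n() + rates.external_input)
            assert abs(resid) < 1e-10 * scale
            assert min(new_state.nh4, new_state.nox, new_state.no3) >= 0

    def test_dead_model_changes_nothing(self, default_params):
        params = replace(
            default_params,
            **{n: 0.0 for n in KMAX_NAMES},
            kmax_n2o_reduction=0.0,
            uptake_nh4=0.0,
            uptake_no3=0.0,
        )
        state = SoilState()
        new_state, flux, _ = step_month(
            state, params, 1.0, None, _forcing_month(nh4_supply=0.0, no3_supply=0.0)
        )
        assert flux == 0.0
        assert new_state.nh4 == state.nh4
        assert new_state.no3 == state.no3

    def test_zero_yields_transform_without_emitting(self, default_params):
        params = replace(
            default_params,
            n2o_yield=replace(
                default_params.n2o_yield,
                ammonia_oxidation=0.0, heterotrophic=0.0,
                nitrifier_denitrification=0.0, denitrifier_denitrification=0.0,
            ),
            kmax_n2o_reduction=0.0,
        )
        state = SoilState(nh4=2.0, no3=3.0)
        new_state, flux, rates = step_month(
            state, params, 1.0, None, _forcing_month()
        )
        assert flux == 0.0
        assert rates.autotrophic_nitrification > 0
        assert new_state.nh4 < state.nh4 + 0.5  # substrate still consumed

    def test_half_step_consistency_annual(self, default_params):
        # documented Euler tolerance with the step-size-sensitive N2O
        # reduction pathway disabled (see methods note)
        params = replace(default_params, kmax_n2o_reduction=0.0)
        half = replace(
            params,
            **{n: getattr(params, n) / 2 for n in KMAX_NAMES},
            uptake_nh4=params.uptake_nh4 / 2,
            uptake_no3=params.uptake_no3 / 2,
        )
        forcing = d.gen_site_forcing(24, seed=1)
        s1, s2 = SoilState(), SoilState()
        full, split = [], []
        for i in range(24):
            fm = forcing.month(i)
            s1, f1, _ = step_month(s1, params, 1.0, None, fm)
            hm = dict(fm)
            hm["nh4_supply"] /= 2
            hm["no3_supply"] /= 2
            s2, fa, _ = step_month(s2, half, 1.0, None, hm)
            s2, fb, _ = step_month(s2, half, 1.0, None, hm)
            full.append(f1)
            split.append(fa + fb)
        annual_full = sum(full[12:])
        annual_split = sum(split[12:])
        assert annual_split == pytest.approx(annual_full, rel=0.10)

    def test_negative_supply_rejected(self, default_params):
        with pytest.raises(ValueError):
            step_month(
                SoilState(), default_params, 1.0, None,
                _forcing_month(nh4_supply=-0.1),
            )


class TestSimulateSite:
    def test_constant_forcing_reaches_steady_flux(self, default_params):
        forcing = SiteForcing(
            temperature=np.full(120, 18.0), moisture=np.full(120, 0.6),
            ph=np.full(120, 5.0), organic_c=np.full(120, 3000.0),
            nh4_supply=np.full(120, 0.5), no3_supply=np.full(120, 0.3),
        )
        flux = d.simulate_site(forcing, default_params)
        assert flux[-1] == pytest.approx(flux[-2], rel=1e-6)
        assert flux[-1] == pytest.approx(flux[-12], rel=1e-4)

    def test_richness_ordering_under_negative_coefficients(
        self, default_params, uniform_fpd, site_forcing
    ):
        annual = [
            d.simulate_site(site_forcing, default_params, richness=r, fpd=uniform_fpd).sum()
            for r in [1, 2, 4, 8, 16, 24]
        ]
        assert np.all(np.diff(annual) < 0)

    def test_deterministic(self, default_params, site_forcing, true_fpd):
        a = d.simulate_site(site_forcing, default_params, richness=8, fpd=true_fpd)
        b = d.simulate_site(site_forcing, default_params, richness=8, fpd=true_fpd)
        np.testing.assert_array_equal(a, b)

    def test_production_linearity_without_reduction(self, default_params):
        # substrate-saturated regime, reduction off: doubling every
        # production K_max doubles the annual emission
        params = replace(default_params, kmax_n2o_reduction=0.0)
        forcing = SiteForcing(
            temperature=np.full(24, 18.0), moisture=np.full(24, 0.6),
            ph=np.full(24, 5.0), organic_c=np.full(24, 30000.0),
            nh4_supply=np.full(24, 50.0), no3_supply=np.full(24, 50.0),
        )
        doubled = params.with_kmax(params.kmax_vector() * 2)
        f1 = d.simulate_site(forcing, params)[12:].sum()
        f2 = d.simulate_site(forcing, doubled)[12:].sum()
        assert f2 == pytest.approx(2 * f1, rel=0.01)

    def test_flux_unit_conversion(self):
        assert d.flux_to_ug_m2_h(0.7305) == pytest.approx(1000.0)


class TestFitDiversityFactor:
    def _table(self, b, levels=(1, 2, 4, 8, 16, 24), noise=None, rng=None):
        rows = []
        for r in levels:
            row = {"richness": r}
            for n in KMAX_NAMES:
                k = 0.3 * r**b
                if noise and r > 1:
                    k *= float(np.exp(rng.normal(0.0, noise)))
                row[n] = k
            rows.append(row)
        return pd.DataFrame(rows)

    def test_exact_power_law_recovered(self):
        fit = d.fit_diversity_factor(self._table(-0.2))
        for n in KMAX_NAMES:
            assert fit.coefficients[n] == pytest.approx(-0.2, abs=1e-10)

    def test_constant_kmax_gives_unity_factor(self):
        fit = d.fit_diversity_factor(self._table(0.0))
        for n in KMAX_NAMES:
            assert fit.coefficients[n] == pytest.approx(0.0, abs=1e-12)
            assert fit.multipliers(16)[n] == pytest.approx(1.0)

    def test_noisy_recovery_unbiased(self):
        estimates = []
        for s in range(50):
            rng = np.random.default_rng(s)
            fit = d.fit_diversity_factor(
                self._table(-0.25, noise=0.05, rng=rng)
            )
            estimates.append(np.mean([fit.coefficients[n] for n in KMAX_NAMES]))
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(estimates.size)
        assert abs(estimates.mean() - (-0.25)) < 3 * se

    def test_missing_baseline_rejected(self):
        table = self._table(-0.2, levels=(2, 4, 8))
        with pytest.raises(ValueError, match="richness-1"):
            d.fit_diversity_factor(table)


class TestParamsIO:
    def test_yaml_round_trip(self, default_params, tmp_path):
        path = tmp_path / "params.yaml"
        d.micn.save_params(default_params, path)
        loaded = d.micn.load_params(path)
        assert loaded == default_params

    def test_unknown_field_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("kmax_nitr_aoa: 0.3\nbogus_field: 1\n")
        with pytest.raises(ValueError, match="bogus_field"):
            d.micn.load_params(path)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("kmax_nitr_aoa", -0.1),
            ("uptake_nh4", 1.5),
        ],
    )
    def test_invalid_parameters_rejected(self, default_params, field, value):
        with pytest.raises(ValueError):
            replace(default_params, **{field: value})
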