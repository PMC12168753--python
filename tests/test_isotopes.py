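"""SP/delta18O source partitioning: isotopocule algebra and inversion."""

import numpy as np
import pytest
import yaml
from dataclasses import replace
from hypothesis import given, settings, strategies as st

import divn2o as d
from divn2o.isotopes import EndmemberSet, IsotopeSample, load_endmember_config


class TestIsotopoculeAlgebra:
    @pytest.mark.parametrize(
        "alpha,beta,sp,bulk",
        [(15.3, 15.3, 0.0, 15.3), (20.0, -10.0, 30.0, 5.0), (-3.0, -3.0, 0.0, -3.0)],
    )
    def test_site_preference_and_bulk(self, alpha, beta, sp, bulk):
        assert d.site_preference(alpha, beta) == pytest.approx(sp)
        assert d.bulk_delta(alpha, beta) == pytest.approx(bulk)

    def test_swap_antisymmetry_and_symmetry(self):
        assert d.site_preference(7.0, 2.0) == -d.site_preference(2.0, 7.0)
        assert d.bulk_delta(7.0, 2.0) == d.bulk_delta(2.0, 7.0)

    def test_non_finite_sample_rejected(self):
        with pytest.raises(ValueError):
            IsotopeSample(delta15N_alpha=np.nan, delta15N_beta=0.0, delta18O=30.0)


class TestEndmembers:
    def test_reference_water_leaves_set_unchanged(self, endmembers):
        adjusted = d.build_endmembers(endmembers, endmembers.d18o_water_reference)
        assert adjusted == endmembers

    def test_water_shift_moves_oxygen_endmembers_only(self, endmembers):
        shift_water = endmembers.d18o_water_reference + 2.0
        adjusted = d.build_endmembers(endmembers, shift_water)
        delta = endmembers.d18o_water_coupling * 2.0
        assert adjusted.d18o_nitrification == pytest.approx(
            endmembers.d18o_nitrification + delta
        )
        assert adjusted.d18o_bacterial_denitrification == pytest.approx(
            endmembers.d18o_bacterial_denitrification + delta
        )
        assert adjusted.sp_nitrification == endmembers.sp_nitrification
        assert adjusted.eps_sp_reduction == endmembers.eps_sp_reduction

    def test_yaml_round_trip(self, endmembers, tmp_path):
        path = tmp_path / "em.yaml"
        payload = {
            "sp_nitrification": {"mean": endmembers.sp_nitrification,
                                 "range": list(endmembers.sp_nitrification_range)},
            "sp_bacterial_denitrification": {
                "mean": endmembers.sp_bacterial_denitrification,
                "range": list(endmembers.sp_bacterial_denitrification_range)},
            "d18o_nitrification": {"mean": endmembers.d18o_nitrification,
                                   "range": list(endmembers.d18o_nitrification_range)},
            "d18o_bacterial_denitrification": {
                "mean": endmembers.d18o_bacterial_denitrification,
                "range": list(endmembers.d18o_bacterial_denitrification_range)},
            "eps_sp_reduction": {"mean": endmembers.eps_sp_reduction,
                                 "range": list(endmembers.eps_sp_reduction_range)},
            "eps_18o_reduction": {"mean": endmembers.eps_18o_reduction,
                                  "range": list(endmembers.eps_18o_reduction_range)},
            "d18o_water_reference": endmembers.d18o_water_reference,
            "d18o_water_coupling": endmembers.d18o_water_coupling,
        }
        path.write_text(yaml.safe_dump(payload))
        assert load_endmember_config(path) == endmembers

    def test_missing_field_named_in_error(self):
        from divn2o.isotopes import _endmembers_from_dict

        with pytest.raises(ValueError, match="sp_bacterial_denitrification"):
            _endmembers_from_dict({"sp_nitrification": 30.0})

    def test_zero_enrichment_rejected(self, endmembers):
        with pytest.raises(ValueError):
            replace(endmembers, eps_sp_reduction=0.0)


class TestPartition:
    def test_sample_at_nitrification_endmember(self, endmembers):
        sample = d.gen_isotope_samples(0.0, 0.0, endmembers)[0]
        part = d.spo_map_partition(sample, endmembers)
        assert part.f_nitrification == pytest.approx(1.0, abs=1e-9)
        assert part.reduced_fraction == pytest.approx(0.0, abs=1e-9)

    def test_sample_at_denitrification_endmember(self, endmembers):
        sample = d.gen_isotope_samples(1.0, 0.0, endmembers)[0]
        part = d.spo_map_partition(sample, endmembers)
        assert part.f_bacterial_denitrification == pytest.approx(1.0, abs=1e-9)
        assert part.reduced_fraction == pytest.approx(0.0, abs=1e-9)

    def test_forward_inverse_round_trip(self, endmembers):
        sample = d.gen_isotope_samples(0.7, 0.2, endmembers)[0]
        part = d.spo_map_partition(sample, endmembers)
        assert part.f_bacterial_denitrification == pytest.approx(0.7, abs=1e-6)
        assert part.reduced_fraction == pytest.approx(0.2, abs=1e-6)
        assert part.feasible

    def test_water_adjustment_round_trips(self, endmembers):
        sample = d.gen_isotope_samples(
            0.4, 0.1, endmembers, soil_water_d18O=-3.5
        )[0]
        part = d.spo_map_partition(sample, endmembers)
        assert part.f_bacterial_denitrification == pytest.approx(0.4, abs=1e-6)
        assert part.reduced_fraction == pytest.approx(0.1, abs=1e-6)

    def test_pure_mixture_has_zero_reduction(self, endmembers):
        for f in np.linspace(0, 1, 7):
            sample = d.gen_isotope_samples(float(f), 0.0, endmembers)[0]
            part = d.spo_map_partition(sample, endmembers)
            assert part.reduced_fraction == pytest.approx(0.0, abs=1e-9)

    @given(
        sp_shift=st.floats(-20, 20),
        o_shift=st.floats(-20, 20),
    )
    @settings(deadline=None, max_examples=40)
    def test_translation_invariance(self, sp_shift, o_shift):
        em = d.default_endmembers()
        sample = d.gen_isotope_samples(0.6, 0.15, em)[0]
        shifted_em = replace(
            em,
            sp_nitrification=em.sp_nitrification + sp_shift,
            sp_bacterial_denitrification=em.sp_bacterial_denitrification + sp_shift,
            d18o_nitrification=em.d18o_nitrification + o_shift,
            d18o_bacterial_denitrification=em.d18o_bacterial_denitrification + o_shift,
            sp_nitrification_range=None,
            sp_bacterial_denitrification_range=None,
            d18o_nitrification_range=None,
            d18o_bacterial_denitrification_range=None,
        )
        bulk = sample.bulk
        shifted_sample = IsotopeSample(
            delta15N_alpha=bulk + (sample.sp + sp_shift) / 2,
            delta15N_beta=bulk - (sample.sp + sp_shift) / 2,
            delta18O=sample.delta18O + o_shift,
        )
        base = d.spo_map_partition(sample, em)
        moved = d.spo_map_partition(shifted_sample, shifted_em)
        assert moved.f_bacterial_denitrification == pytest.approx(
            base.f_bacterial_denitrification, abs=1e-9
        )
        assert moved.reduced_fraction == pytest.approx(
            base.reduced_fraction, abs=1e-9
        )

    def test_degenerate_geometry_rejected(self, endmembers):
        # reduction vector parallel to the mixing line
        d_sp = endmembers.sp_bacterial_denitrification - endmembers.sp_nitrification
        d_o = (
            endmembers.d18o_bacterial_denitrification
            - endmembers.d18o_nitrification
        )
        parallel = replace(
            endmembers,
            eps_sp_reduction=d_sp,
            eps_18o_reduction=d_o,
            eps_sp_reduction_range=None,
            eps_18o_reduction_range=None,
        )
        sample = d.gen_isotope_samples(0.5, 0.0, endmembers)[0]
        with pytest.raises(ValueError, match="degenerate"):
            d.spo_map_partition(sample, parallel)

    def test_infeasible_sample_flagged_not_clipped(self, endmembers):
        sample = IsotopeSample(
            delta15N_alpha=60.0, delta15N_beta=-40.0, delta18O=80.0
        )  # SP = 100, far outside the endmember region
        part = d.spo_map_partition(sample, endmembers)
        assert not part.feasible
        assert not (0 <= part.f_bacterial_denitrification <= 1) or not (
            0 <= part.reduced_fraction < 1
        )


class TestMonteCarlo:
    def test_zero_width_ranges_match_deterministic(self, endmembers):
        narrow = replace(
            endmembers,
            sp_nitrification_range=None,
            sp_bacterial_denitrification_range=None,
            d18o_nitrification_range=None,
            d18o_bacterial_denitrification_range=None,
            eps_sp_reduction_range=None,
            eps_18o_reduction_range=None,
        )
        sample = d.gen_isotope_samples(0.65, 0.1, narrow)[0]
        det = d.spo_map_partition(sample, narrow)
        mc = d.monte_carlo_partition(sample, narrow, n_draws=500, seed=0)
        assert mc.f_bacterial_denitrification == pytest.approx(
            det.f_bacterial_denitrification, abs=1e-12
        )
        assert mc.uncertainty["f_bacterial_denitrification"] == 0.0
        assert mc.feasible_fraction == 1.0

    def test_fixed_seed_reproducible(self, endmembers):
        sample = d.gen_isotope_samples(0.6, 0.15, endmembers)[0]
        a = d.monte_carlo_partition(sample, endmembers, n_draws=2000, seed=11)
        b = d.monte_carlo_partition(sample, endmembers, n_draws=2000, seed=11)
        assert a.f_bacterial_denitrification == b.f_bacterial_denitrification
        assert a.reduced_fraction == b.reduced_fraction

    def test_draw_count_convergence(self, endmembers):
        sample = d.gen_isotope_samples(0.6, 0.15, endmembers)[0]
        small = d.monte_carlo_partition(sample, endmembers, n_draws=10_000, seed=1)
        large = d.monte_carlo_partition(sample, endmembers, n_draws=100_000, seed=2)
        se = small.uncertainty["f_bacterial_denitrification"] / np.sqrt(
            10_000 * small.feasible_fraction
        )
        assert abs(
            small.f_bacterial_denitrification - large.f_bacterial_denitrification
        ) < 3 * se

    def test_noisy_sample_mean_recovery(self, endmembers):
        samples = d.gen_isotope_samples(0.7, 0.2, endmembers, noise_sd=0.5, n=200, seed=5)
        f_bd = np.array(
            [d.spo_map_partition(s, endmembers).f_bacterial_denitrification
             for s in samples]
        )
        se = f_bd.std(ddof=1) / np.sqrt(f_bd.size)
        assert abs(f_bd.mean() - 0.7) < 3 * se

    def test_too_few_draws_rejected(self, endmembers):
        sample = d.gen_isotope_samples(0.5, 0.1, endmembers)[0]
        with pytest.raises(ValueError):
            d.monte_carlo_partition(sample, endmembers, n_draws=50)
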