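# divn2o

Tree species richness is a major, and usually ignored, control on nitrous
oxide (N₂O) emissions from forest soils: mixed-species forests emit less
N₂O than monocultures, mainly because trees competing for soil inorganic
nitrogen starve the denitrifiers that produce it. `divn2o` implements the
full computational chain needed to quantify that effect, from field data
to global scenario totals, for ecosystem biogeochemists and modellers:

1. **Effect-size meta-analysis** (`divn2o.meta`) — paired
   monoculture/mixture observations are converted to standardized mean
   differences, SMD = (X̄_T − X̄_C)/SD_pooled (Hedges' g by default),
   pooled per richness subgroup with a DerSimonian–Laird random-effects
   model, and regressed on log₂(richness) by weighted least squares.
2. **Static-chamber fluxes** (`divn2o.chamber`) — headspace N₂O
   concentrations sampled at 0/10/20/30/40 min become fluxes via
   f = ρ·h·dC/dt with the ideal-gas N₂O density ρ(T, P), plus the terrain
   slope factor S = (θ/10)^0.78, seasonal aggregation (growing season
   April–October) and Kruskal–Wallis tests across diversity levels.
3. **Isotope source partitioning** (`divn2o.isotopes`) — the N₂O site
   preference SP = δ¹⁵Nᵅ − δ¹⁵Nᵝ and δ¹⁸O place each sample in the SP/O
   plane, where a two-endmember production mixture (nitrification vs
   bacterial denitrification) displaced along a Rayleigh reduction vector
   (δ = δ_mix + ε·ln(1 − reduced fraction)) has a closed-form inverse;
   endmember uncertainty propagates by Monte Carlo.
4. **A diversity-scaled microbial N-cycle model** (`divn2o.micn`) —
   monthly NH₄⁺/NOx/NO₃⁻/N₂O pools driven by four
   Michaelis–Menten pathways (autotrophic and heterotrophic
   nitrification, nitrifier and denitrifier denitrification) with Q10,
   moisture and pH response scalars. Each of the six maximum pathway rates
   K_max is multiplied by a tree-diversity factor F_PD(r) = r^b anchored
   at F_PD(1) = 1.
5. **Surrogate Bayesian calibration** (`divn2o.calibrate`) — the six
   K_max are fitted to monthly flux observations with a Gaussian-process
   assisted optimizer (Latin-hypercube seeding, expected-improvement
   exploration, damped least-squares refinement), a 70/30
   train–validation split, and R²/RMSE reporting; per-richness
   calibrations feed the F_PD fit.
6. **Gridded scenarios** (`divn2o.gridsim`) — the calibrated model runs
   cell-by-cell over monthly lat/lon forcing under uniform-richness
   counterfactuals (1–24 species), aggregated with spherical cell areas to
   global and climate-zone totals in Tg N yr⁻¹ and reduction percentages
   relative to monoculture.

A synthetic-data module (`divn2o.synthetic`) generates every input class
with known ground truth, so the whole chain is testable offline, and
`divn2o.pipeline` orchestrates all stages with seeds, manifests and
SHA-256 digests.

## Worked example

```python
import divn2o as d

# meta-analysis of a synthetic 201-study data set (true slope -0.3)
obs = d.gen_meta_dataset(d.SynthMetaSpec(true_slope=-0.3, seed=1))
fit = d.meta_analyze(obs)["fit"]
print(f"slope {fit.slope:+.3f} ± {fit.slope_se:.3f} per log2(richness), R² {fit.r_squared:.3f}")
# slope -0.273 ± 0.066 per log2(richness), R² 0.852

# one noisy chamber deployment with a true flux of 12.5 µg m⁻² h⁻¹
series = d.gen_chamber_series(12.5, height=0.3, temperature=25.0, noise_sd=1.0, seed=7)
est = d.chamber_flux(series)
print(f"flux {est.flux:.2f} µg N2O m⁻² h⁻¹ (fit R² {est.fit_r_squared:.3f})")
# flux 11.82 µg N2O m⁻² h⁻¹ (fit R² 0.997)

# isotope source partitioning with endmember uncertainty
em = d.default_endmembers()
sample = d.gen_isotope_samples(0.7, 0.2, em, noise_sd=0.3, seed=2)[0]
part = d.monte_carlo_partition(sample, em, n_draws=10_000, seed=0)
print(f"bacterial denitrification {part.f_bacterial_denitrification:.2f} "
      f"± {part.uncertainty['f_bacterial_denitrification']:.2f}, "
      f"reduced fraction {part.reduced_fraction:.2f}")
# bacterial denitrification 0.71 ± 0.09, reduced fraction 0.25
```

The slope says each doubling of tree species lowers the standardized N₂O
effect size by ≈0.27; the subgroup CIs all exclude zero, i.e. every
mixture level emits significantly less than monoculture. The partition
says ~71 % of gross N₂O production at this plot comes from bacterial
denitrification and a quarter of the produced N₂O is consumed again
before escaping.

The end-to-end pipeline (synthetic data → meta-analysis → fluxes →
isotopes → calibration → global scenarios) runs from a YAML config:

```bash
divn2o run --config pipeline.yaml        # or: python -m divn2o.cli
```

Each stage also has its own subcommand (`divn2o synth|meta|flux|isotopes|
calibrate|simulate-site|simulate-global`).

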