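# Methods

This note records the scientific and numerical choices behind `divn2o`:
the statistical procedures, the process-model equations and their
assumptions, the parameters that matter, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Effect-size meta-analysis

Each paired observation compares the mean soil N₂O flux of a
single-species (control) and a mixed-species (treatment) forest stand.
The effect size is the standardized mean difference

    SMD = (X̄_T − X̄_C) / SD_pooled,
    SD_pooled = sqrt(((n_C−1)s_C² + (n_T−1)s_T²) / (n_C + n_T − 2)).

Because forest-plot replicate counts are small (typically 3–6), the
Hedges correction J = 1 − 3/(4(n_C+n_T−2) − 1) is applied by default
(`hedges=False` gives Cohen's d). The per-effect sampling variance is
(n_C+n_T)/(n_C·n_T) + SMD²/(2(n_C+n_T)).

Subgroups (one per treatment richness) are pooled with a
DerSimonian–Laird random-effects model (τ² by the method-of-moments
estimator, I² reported). Two details matter for accuracy at these sample
sizes:

* **Two-pass pooling.** Evaluating the SMD² term of each study's variance
  at the study's own effect makes weights correlate with effects and
  shrinks pooled subgroup means toward zero; in simulation this
  attenuated the diversity-response slope by ~12 % and dropped CI
  coverage from ~95 % to 84 %. The pooling therefore re-evaluates the
  variance at the subgroup's pooled effect (one extra pass) whenever
  replicate counts are available. Coverage of the regression CI is then
  ~94–95 % in 200-replicate simulations.
* **Weighted regression.** The diversity response is fitted as subgroup
  mean effect vs log₂(richness) by weighted least squares with weights
  1/SE² (the subgroup standard errors), the default reading of a
  weighted fit to mean values and standard errors; fitting the raw
  per-study effects with inverse-variance weights is also supported
  through the same function.

## Chamber fluxes

The flux of a closed static chamber is f = ρ·h·dC/dt, with dC/dt the
ordinary-least-squares slope of the five-point (0/10/20/30/40 min)
concentration series in ppb min⁻¹, h the chamber height and ρ the
ideal-gas density of N₂O at chamber temperature
(ρ = P·M/(R·T), M = 44.013 g mol⁻¹; chamber pressure is assumed to be
one standard atmosphere because deployments rarely record it). The unit
chain ppb min⁻¹ → µg m⁻² h⁻¹ is f = ρ[g m⁻³]·h[m]·slope·6×10⁻².
Fits with R² < 0.90 are flagged, never dropped; a perfectly constant
series is defined to have slope 0 and R² 1. Terrain correction uses the
slope factor S = (θ/10)^0.78; whether a study multiplies or divides by S,
and whether it applies S to fluxes or only to soil properties, varies in
practice, so both modes exist with multiply as the documented default and
the mode recorded in the output. Growing season is April–October.
Differences across diversity levels use the tie-corrected Kruskal–Wallis
test (flux distributions are skewed).

## Isotope source partitioning (SP/O map)

N₂O carries two independent pathway tracers: the site preference
SP = δ¹⁵Nᵅ − δ¹⁵Nᵝ (δ¹⁵N_bulk = (δ¹⁵Nᵅ+δ¹⁵Nᵝ)/2) and δ¹⁸O. Production
is modelled as a two-endmember mixture — nitrification
(hydroxylamine-oxidation, high SP) vs bacterial denitrification (SP ≈ 0)
— and partial reduction of N₂O to N₂ displaces the residual gas along a
Rayleigh vector:

    δ_measured = f_bD·δ_bD + (1−f_bD)·δ_Ni + ε · ln(1 − reduced_fraction)

on both axes, with pathway-specific enrichment factors ε (negative under
the residual-enrichment convention used here: closed-system Rayleigh,
δ = δ₀ + ε·ln r with r the unreduced fraction). Requiring the same
ln r on both axes makes f_bD the solution of a linear equation and
reduced_fraction = 1 − exp((SP_m − SP_mix)/ε_SP). Geometric degeneracy
(mixing line parallel to the reduction vector) is an explicit error;
solutions outside [0,1] are reported as infeasible, never clipped,
because clipping would bias Monte-Carlo means.

δ¹⁸O endmembers are adjusted for the local soil-water δ¹⁸O (most N₂O
oxygen exchanges with water): both means and ranges shift by
coupling × (δ¹⁸O_water − reference), with full coupling by default. SP
endmembers are never adjusted, as SP is substrate-independent.

Endmember means, ranges and ε values are *inputs*, shipped in
`src/divn2o/data/endmembers.yaml` with literature-typical values
(SP_Ni = 32.8 ‰, SP_bD = −1.6 ‰, δ¹⁸O_Ni = 35 ‰, δ¹⁸O_bD = 10.8 ‰,
ε_SP = −5.9 ‰, ε_18O = −15.4 ‰) that site studies should replace with
their own calibrated set. Uncertainty propagation draws uniformly over
the declared ranges, discards infeasible draws, and reports means, SDs
and the feasible fraction. Fractions are expressed relative to gross N₂O
production (f_Ni + f_bD = 1), with reduction as the fraction of gross
production consumed.

## The diversity-scaled microbial nitrogen model

State (per m² of 0–10 cm topsoil, g N): NH₄⁺, a lumped nitrite/NOx pool,
NO₃⁻, and a transient N₂O pool vented each month. Monthly NH₄⁺ and NO₃⁻
forcing values are interpreted as substrate *supplies*
(g N m⁻² month⁻¹) — mineralization, deposition, throughfall — added to
the pools; users holding concentration products instead need a turnover
conversion. Pathways, each K_max × MM(substrate) × environmental
scalars:

| pathway | substrate | products | K_max |
|---|---|---|---|
| AOA ammonia oxidation | NH₄⁺ (K_h 0.3) | NOx (+ yield·N₂O) | K_max_Nitr_AOA |
| AOB ammonia oxidation | NH₄⁺ (K_h 1.2) | NOx (+ yield·N₂O) | K_max_Nitr_AOB |
| nitrite oxidation (NOB) | NOx | NO₃⁻ | K_max_Nitr_NOB |
| heterotrophic nitrification | NH₄⁺, organic C | NO₃⁻ (+ yield·N₂O) | K_max_NitrH |
| nitrifier denitrification | NOx | N₂O / N₂ by yield | K_max_NOx_AOB |
| denitrifier denitrification | NO₃⁻, organic C | N₂O / N₂ by yield | K_max_NOx_Denitr |
| N₂O reduction | N₂O pool | N₂ | kmax_n2o_reduction |

Environmental scalars: f_T = Q10^((T−T_ref)/10) (Q10 = 2, T_ref = 15 °C;
exceeds 1 above the reference); nitrification moisture response is
Gaussian around an optimum (0.60 water-filled pore fraction, width 0.25)
while the denitrification response rises monotonically (moisture²); pH
responses are Gaussian with guild-specific optima — AOA 4.7, AOB 5.6,
heterotrophic (fungal) nitrifiers 4.6, generic 5.2 — reflecting AOA and
fungal dominance in acidic forest topsoils. First-order plant-uptake and
leaching sinks act on NH₄⁺ (0.40 month⁻¹) and NO₃⁻ (0.25 month⁻¹); plant
competition for inorganic N is precisely the mechanism by which richness
suppresses denitrification, so these sinks belong in the model even
before diversity scaling.

The tree-diversity factor multiplies each K_max by F_PD(r) = r^(b_p),
one coefficient per pathway, anchored at F_PD(1) = 1 (linear in
log₂-richness space, consistent with the log₂ treatment used throughout
the analysis chain). `fit_diversity_factor` recovers b_p as the
through-origin least-squares slope of log₂(K(r)/K(1)) on log₂(r), with
per-pathway coefficient SEs.

Integration is explicit Euler at monthly resolution. Competing demands
on each pool (including uptake) are scaled proportionally when they
exceed availability, so pools cannot go negative, and the nitrogen budget
(pool change + emission + N₂ loss + uptake = supply) closes to machine
precision every step — the test suite checks 10⁻¹⁰ relative over 1000
randomized states. Two numerical caveats are documented rather than
hidden: (i) the monthly venting of the transient N₂O pool makes the
*reduction* pathway step-size sensitive (its MM term sees the whole
month's production at once), so the half-step consistency check is run
with reduction disabled, where annual fluxes agree within ~4 %
(tolerance 10 % in the test); (ii) all four production pathways are
first-order in their K_max, so with reduction disabled and substrates
saturating, emissions scale exactly linearly under a common K_max
multiplier (verified numerically to 1 %).

**Identifiability by design.** The six K_max must be recoverable from
monthly flux series, or calibration is meaningless. Three structural
choices make the inverse problem well-posed, verified by SVD of the
residual Jacobian (condition number ~10²) and by exact parameter recovery
from noiseless data: the uptake sinks keep the NO₃⁻ pool in the curved
part of its MM response instead of accumulating without bound; the
nitrite pool has month-scale memory (half-saturation 0.25 g N m⁻²), so
the *absolute* rates of its two consumers (NOB vs nitrifier
denitrification) imprint on the flux timeline rather than only their
ratio; and the guild-specific half-saturations and pH optima separate
AOA from AOB, which would otherwise be exactly collinear. Calibrating
against observations from several richness levels jointly (with the
per-pathway F_PD known or co-fitted) sharpens this further, because each
level reweights the pathways differently.

## Calibration

The loss is the RMSE of predicted vs observed monthly fluxes on the
training split (70/30 observation-level split by default, seeded).
Search is over a box (default [0.02, 1.5] g N m⁻² month⁻¹ per K_max —
roughly an order of magnitude either side of plausible forest-topsoil
rates) on a log scale. The optimizer is sequential model-based with a
division of labour:

1. Latin-hypercube seeding (default 30 points), plus warm starts — the
   prior parameterization always, and e.g. the previous richness level's
   fit in per-richness calibration.
2. Expected-improvement proposals from a Gaussian-process surrogate
   (Matérn 5/2 + white noise, fitted to the log-loss in the normalized
   box) over global and incumbent-local candidates — about 5 % of the
   budget.
3. Local refinement of up to three diverse starts (seeding-phase best
   first, then distinct incumbents): damped least squares
   (Levenberg–Marquardt-type, exploiting the sum-of-squares structure)
   when residuals are available, Nelder–Mead otherwise. Each start may
   use the whole remaining refinement budget; later starts run on what
   early terminators leave.
4. The final `n_average` evaluations sample tightly around the converged
   incumbent, and the returned parameter vector is the mean of those
   final proposals — a converged point estimate rather than an
   exploration average. (A mean-of-the-n-best variant is available via
   `average_best`.) Runs at the scale used in the tests average the final
   30 of 300 iterations, the same 10 % tail fraction as a
   1000-iteration/final-100 schedule.

Rationale for step 3: pure surrogate exploitation repeatedly polished a
broad, shallow secondary basin of the RMSE surface (R² ≈ 0.999 with
parameters far off), while the deep global basin is narrow; the
least-squares geometry finds it reliably from diverse starts. Non-finite
objective values are penalized, never raised. Everything is deterministic
given the spec seed; the optimizer never proposes outside the box.

Under the reference conditions used in the tests (36-month forcing, six
richness levels, noiseless observations, 300 evaluations), all six K_max
are recovered to well under 1 % at the default seed, and within 10 % in
8–10 of 10 seeds depending on configuration; held-out R² is ≈1.0.

## Gridded scenarios

Cell areas use the spherical band formula
A = R²·Δλ·(sin φ₂ − sin φ₁) (R = 6371 km); summed over a full 1°×1°
grid this reproduces the Earth's surface area (5.1007×10¹⁴ m²) to
rounding. Each forest cell is spun up by cycling its first forcing year
until the annual flux changes by < 0.1 % (max 20 cycles; initial pools
are not observable), then simulated over the forcing period; annual
totals are Σ cells Σ months flux·area ×10⁻¹², in Tg N yr⁻¹. Scenarios
impose a uniform richness on every forest cell (a counterfactual design;
observed-richness maps are out of scope). Reductions are
100·(1 − total(r)/total(1)). Climate zones default to
tropical/subtropical where |lat| ≤ 30° when no zone raster is supplied;
both the boundary and the zone field are configurable inputs. Grid I/O
is CF-style NetCDF (classic format via the scipy engine) with a variable
alias map so real forcing products can be loaded under their native
names.

## Synthetic data: what it does and does not emulate

All generators are pure functions of (spec, seed) and their outputs pass
the consuming modules' validation. Ground truth is always recoverable:
noiseless chamber series and isotope samples invert exactly (the
generators are literal inverses of the analysis equations), and
noiseless model observations equal `simulate_site` output bit-for-bit.

* Paired meta-observations: the true effect at treatment richness r is
  intercept + slope·log₂(r) (defaults 0 and −0.3) plus Gaussian
  between-study heterogeneity (SD 0.15); group means and SDs are
  empirical moments of simulated plot replicates (3–6 per arm), control
  fluxes lognormal around ~8 µg m⁻² h⁻¹ with within-group SD 35 % of the
  mean. 201 studies by default, over richness levels {2,4,8,16,24}
  (treatments of the {1,2,4,8,16,24} experimental design).
* Site forcing: one annual sinusoid per variable with staggered peak
  months (temperature July, moisture September, pH March, organic C
  November, NH₄⁺ supply May, NO₃⁻ supply October) plus small Gaussian
  noise, clipped to declared ranges chosen for an acidic subtropical
  forest topsoil (pH 4.5–5.6, supplies ≤0.8 g N m⁻² month⁻¹). The
  stagger is deliberate: collinear drivers would blur pathway
  identifiability.
* Grid forcing: the same sinusoids per cell, temperature cooling
  poleward and phase-flipping in the southern hemisphere, a Bernoulli
  forest mask and |lat|-threshold climate zones. No attempt is made to
  mimic the spatial covariance of real climatology products, so passing
  tests demonstrate correctness of the computational chain, not realism
  of any absolute global total.
* Model observations: `simulate_site` output per richness level plus
  optional Gaussian noise. The pipeline's synthetic truth uses K_max
  deliberately offset ~25 % from the packaged defaults (so calibration
  is tested against a truth it does not start from) and
  denitrification-dominant diversity coefficients (b = −0.35 and −0.20
  for the two denitrification pathways vs −0.05 to −0.10 for the
  nitrification pathways), consistent with the mechanism that declining
  inorganic N suppresses denitrification first. With these conditions
  the 24-species scenario reduces emissions by ~64 % relative to
  monoculture — somewhat above field-calibrated estimates; matching
  those more closely under synthetic forcing would have required
  inverting the pathway ordering, so the mechanism-consistent defaults
  were kept.

## Known limitations

* The kinetic forms and constants of the process model are conventional
  surrogate choices (versioned in `src/divn2o/data/micn_params.yaml`);
  alternative forms are config swaps, not code changes.
* Monthly explicit Euler with a vented N₂O pool makes the reduction
  pathway's step response resolution-dependent (see above); sub-monthly
  dynamics, soil heat/water transport, CO₂/CH₄ and explicit microbial
  biomass pools are out of scope.
* The SP/O plane resolves two production endmembers; fungal
  denitrification and abiotic hybrid pathways are lumped into them.
* Scenario totals inherit the synthetic grid's arbitrary forest mask and
  supply fields; only ratios (reductions, zonal shares) and the
  computational chain itself are meaningful test targets.
* Measurement-error magnitudes for isotopes and chamber concentrations
  are not well constrained by published tables; the generator defaults
  (0.3–0.5 ‰, 1–2 ppb) are placeholders that users should set from their
  instrument precision.
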