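# Default MicN-SR parameterization (schema_version 1).
#
# K_max values are maximum substrate-saturated oxidation/reduction rates in
# g N m-2 month-1 for the 0-10 cm soil layer; half-saturations in the units
# of their substrate pool (g N m-2, organic C in g C m-2); yields are the
# fractions of pathway nitrogen throughput emitted as N2O.  Environmental
# responses: Q10 temperature, Gaussian moisture optimum for nitrification,
# power-law moisture response for denitrification, Gaussian pH responses
# with guild-specific optima for AOA (acid-tolerant) and AOB.
# All values are conventional surrogate choices for an acidic subtropical
# forest topsoil and are meant to be replaced by calibration.
schema_version: 1
kmax_nitr_aoa: 0.35
kmax_nitr_aob: 0.25
kmax_nitr_nob: 0.50
kmax_nitrh: 0.30
kmax_nox_denitr: 0.40
kmax_nox_aob: 0.15
kmax_n2o_reduction: 0.10
uptake_nh4: 0.40
uptake_no3: 0.25
half_saturation:
  nh4_aoa: 0.3
  nh4_aob: 1.2
  nh4_h: 1.0
  nox: 0.25
  no3: 1.5
  organic_c: 1500.0
  n2o: 0.05
n2o_yield:
  ammonia_oxidation: 0.02
  heterotrophic: 0.05
  nitrifier_denitrification: 0.60
  denitrifier_denitrification: 0.25
env:
  t_ref: 15.0
  q10: 2.0
  moisture_opt_nitr: 0.60
  moisture_width_nitr: 0.25
  moisture_exp_denitr: 2.0
  ph_opt: 5.2
  ph_width: 1.5
  ph_opt_aoa: 4.7
  ph_width_aoa: 0.9
  ph_opt_aob: 5.6
  ph_width_aob: 0.8
  ph_opt_het: 4.6
  ph_width_het: 1.0
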