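# SP/O MAP endmember configuration (per mil).
#
# These are literature-typical values for the two N2O production endmembers
# (nitrification via hydroxylamine oxidation; bacterial denitrification) and
# for the Rayleigh enrichment factors of N2O reduction to N2.  They are
# deliberately shipped as *replaceable inputs*: site-specific studies should
# substitute their own calibrated means and ranges.
#
# Conventions:
#   - SP referenced to AIR-N2, delta18O to VSMOW.
#   - Enrichment factors follow the residual-enrichment convention
#     delta_residual = delta0 + eps * ln(r), r = unreduced fraction, eps < 0.
#   - delta18O endmembers are expressed for soil water at
#     d18o_water_reference; build_endmembers() shifts them by
#     d18o_water_coupling * (observed soil-water d18O - reference).
sp_nitrification:
  mean: 32.8
  range: [27.0, 37.0]
sp_bacterial_denitrification:
  mean: -1.6
  range: [-8.0, 3.0]
d18o_nitrification:
  mean: 35.0
  range: [30.0, 40.0]
d18o_bacterial_denitrification:
  mean: 10.8
  range: [6.0, 16.0]
eps_sp_reduction:
  mean: -5.9
  range: [-8.2, -2.9]
eps_18o_reduction:
  mean: -15.4
  range: [-25.0, -5.0]
d18o_water_reference: -8.0
d18o_water_coupling: 1.0
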