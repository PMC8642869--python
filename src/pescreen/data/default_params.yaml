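# Synthetic default parameters for the competing-risks screening model.
#
# These are a documented stand-in, NOT fitted coefficients from any
# published or proprietary risk calculator: the prior baseline mean and the
# no-PE boundary are calibrated so that the population-average prior mass
# below 37 weeks is 1.34% (preterm PE) and below the boundary is 3.17%
# (total PE) under the packaged cohort marginals; effect sizes and marker
# slopes are order-of-magnitude plausible and chosen so the four markers
# have the informativeness ordering MAP < UtAPI < PlGF with PAPP-A adding a
# modest independent contribution. Marker SDs are the unaffected-pregnancy
# log10 MoM SDs of the emulated cohort.
schema_version: 1
prior:
  baseline_mean_weeks: 53.2755   # calibrated, see docs/methods.md
  sd_weeks: 7.0
  effects:                    # additive shifts (weeks) of the prior mean
    chronic_hypertension: -10.0
    diabetes: -4.0
    sle_aps: -5.0
    smoker: -1.0
    conception_assisted: -1.0
    parity_parous_no_pe: 2.0
    parity_parous_previous_pe: -7.0
  slopes:                     # slope (weeks per unit) around a center value
    age_years: {slope: -0.05, center: 31.0}
    weight_kg: {slope: -0.06, center: 63.1}
    height_cm: {slope: 0.06, center: 159.5}
grid: {min: 24.0, max: 60.0, step: 0.02}
preterm_cutoff_weeks: 37.0
no_pe_boundary_weeks: 39.8056    # calibrated, see docs/methods.md
markers:
  # E[log10 MoM | g] = intercept + slope * max(0, knot - g); sd on log10 scale
  MAP:   {intercept: 0.0, slope: 0.005,  knot: 40.0, sd: 0.0307}
  UtAPI: {intercept: 0.0, slope: 0.038,  knot: 40.0, sd: 0.1325}
  PAPPA: {intercept: 0.0, slope: -0.078, knot: 40.0, sd: 0.2550}
  PlGF:  {intercept: 0.0, slope: -0.088, knot: 40.0, sd: 0.2153}
correlations:
  PAPPA:PlGF: 0.1
  MAP:UtAPI: 0.1
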