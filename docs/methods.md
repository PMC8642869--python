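# Methods

This note documents the models implemented in `pescreen`, the packaged
default parameters and why they were chosen, the numerical conventions, and
what the synthetic-data results do and do not establish about real cohorts.

## The competing-risks risk model

The engine follows the competing-risks formulation used in first-trimester
preeclampsia screening. The gestational age at which delivery with PE would
occur, `g` (weeks), is latent:

- **Prior.** `g ~ N(μ(x), σ²)` with `μ(x) = μ₀ + Σ effects(x)`. Effects are
  additive shifts in weeks for history factors (chronic hypertension,
  diabetes, SLE/APS, parity class, assisted conception, smoking) plus linear
  terms in age, weight and height around centering constants. A lower mean
  means earlier — hence likelier preterm — PE.
- **Competing outcome.** Values of `g` at or beyond the no-PE boundary
  represent pregnancies that deliver without ever developing PE. The
  boundary's prior mass is *retained in the normalization*; this is what
  makes the model competing-risks rather than a simple truncated prior.
- **Likelihood.** The log₁₀ MoM vector of the measured markers is
  multivariate Gaussian with broken-stick means
  `E[log₁₀ MoM_m | g] = intercept_m + slope_m · max(0, knot_m − g)` and a
  fixed covariance. Intercepts are 0 by default so unaffected pregnancies
  (g ≥ knot) center on 1 MoM. Missing markers are marginalized out
  (covariance sub-matrix); nothing is imputed.
- **Posterior.** The preterm-PE risk is the posterior mass of `g` below the
  37-week cutoff. With no markers the posterior reduces exactly to the
  prior, and the risk to `Φ((37 − μ)/σ)`.

### Numerical conventions

- Integration grid `g ∈ [24, 60]` weeks, step 0.02, Simpson's rule. Simpson
  (error `O(h⁴)`) was chosen over the trapezoid because narrow posteriors
  (prior SD of a few weeks times several informative markers) need ~1e-6
  absolute accuracy on the risk at this step size; measured agreement with a
  10×-finer midpoint integrator is better than 1e-5 and with the conjugate
  closed form (linear marker mean) better than 1e-6.
- Analytic Gaussian tails outside the grid: above `g_max` the marker means
  are constant (the grid must cover every knot), so the upper-tail term
  `L(z | g_max) · (1 − Φ((g_max − μ)/σ))` is exact; below `g_min` the
  likelihood is frozen at its `g_min` value, a documented approximation that
  only matters for priors with substantial mass before 24 weeks. The tails
  make the empty-marker posterior equal the untruncated prior risk exactly.
- Likelihoods are evaluated in log space with a per-woman max-shift before
  exponentiation; an underflowed normalizer raises a diagnostic error
  (grid too narrow / extreme MoMs) rather than returning garbage.
- Display form "1:N" uses `N = round(1/p)` half-away-from-zero with
  `N ≥ 1`. Classification always compares the raw probability to `1/N`
  (inclusive: risk ≥ 1/100 is high risk); the rounded display is never used
  for classification.

### Default parameters are synthetic stand-ins

Published screening algorithms of this family keep their fitted coefficients
in proprietary software, so `data/default_params.yaml` is a self-consistent
synthetic parameter set, not a reproduction:

- `μ₀ = 53.2755`, `σ = 7` weeks; no-PE boundary `39.8056` weeks. The
  baseline mean and boundary were calibrated once, by root-finding against
  the population-average prior mass over 2×10⁶ sampled profiles, so that
  P(g < 37) = 1.34% and P(g < boundary) = 3.17% — the preterm and total PE
  incidences of the emulated cohort.
- History effects (weeks): chronic hypertension −10, previous PE −7,
  SLE/APS −5, diabetes −4, parous without PE +2, assisted conception −1,
  smoking −1; slopes −0.05/year (age), −0.06/kg, +0.06/cm. Signs follow the
  epidemiology (hypertension, previous PE, diabetes, higher weight and
  shorter stature raise risk; a previous unaffected pregnancy lowers it);
  magnitudes are order-of-magnitude plausible, e.g. they imply ~33% total-PE
  risk with chronic hypertension and ~20% with previous PE.
- Marker SDs (log₁₀ MoM) are the unaffected-pregnancy values of the
  emulated cohort: MAP 0.0307, UtAPI 0.1325, PAPP-A 0.2550, PlGF 0.2153.
  All knots are 40 weeks. Slopes (per week below the knot): MAP +0.005,
  UtAPI +0.038, PAPP-A −0.078, PlGF −0.088; correlations
  ρ(PAPP-A, PlGF) = 0.1, ρ(MAP, UtAPI) = 0.1, others 0.
  The slopes were chosen so that (i) single-marker informativeness is
  ordered MAP < UtAPI < PlGF with PAPP-A contributing modest independent
  information, matching the qualitative pattern of reported detection-rate
  ladders, and (ii) each adjacent step of the detection-rate ladder exceeds
  its Monte-Carlo standard deviation at the evaluation scale (20,000
  pregnancies, ≈250 preterm cases) by a factor ≥ ~2.2, so the ordering is a
  stable property of the defaults rather than a coin flip. Under these
  defaults the simulated AUC is ≈0.75 for history alone and ≈0.97 for
  history plus all four markers.

## MoM computation, QC and re-centering

`compute_mom` divides a raw measurement by the expected median
`10^(poly(ga) + Σ adjustments)`, a degree-≤3 polynomial in gestational age
plus additive log₁₀ covariate adjustments (weight slope, smoking, assisted
conception, diabetes, ethnicity tag). The package applies such models; it
does not fit them.

QC tests the mean of the log₁₀ MoMs of unaffected pregnancies against zero
(one-sample t-test, two-sided, α = 0.05, also available in summary-statistic
form), but *corrects* by dividing all MoMs by the **median** of the
unaffected MoM distribution. Both statistics are carried in the report so
the mean-vs-median asymmetry of the conventional procedure stays visible —
for a skewed distribution the re-centered geometric mean will generally not
be exactly 1.

A statistically significant but clinically negligible shift is left
uncorrected: re-centering is skipped when the median lies within
[0.98, 1.02] (configurable; pass `clinical_band=None` to re-center on
significance alone). This mirrors the practice of leaving markers with
medians of 0.99 MoM untouched despite p < 0.001 at large n. Re-centering is
idempotent and scale-equivariant, and when applied forces the empirical
median to 1 exactly (up to one ulp for even n).

## Synthetic cohorts

The generator realizes the model under study-like marginals:

- Profiles: age N(30.91, 4.03²) truncated to [18, 45], weight
  N(63.10, 10.90²) on [35, 120], height N(159.51, 5.53²) on [140, 185]
  (units: years, kg, cm); prevalences — chronic hypertension 1.61%,
  diabetes 2.84%, SLE/APS 0.32%, assisted conception 5.21%, smoking 0%;
  parity 60.2% / 38.1% / 1.7% (nulliparous / parous no PE / previous PE).
  Covariates are sampled independently: only the *marginals* of the
  emulated cohort are reproduced, and any profile–outcome association
  arises through the prior, not by construction.
- `g` is drawn from the prior; outcome labels follow from the cutoffs
  (preterm PE < 37 ≤ term PE < 39.81 ≤ no PE). PE pregnancies deliver at
  `g`; unaffected pregnancies draw delivery from N(272, 12²) days truncated
  to [196, 294]. Screening age is uniform over 11⁺⁰–13⁺⁶ weeks.
- log₁₀ MoMs are drawn from the marker likelihood at `g` (unaffected women
  from the zero-mean distribution), then multiplied by the configurable
  per-marker `mom_shift` to emulate population-level miscentering.
- Aspirin: after risks are computed and the 1:100 classification applied,
  each high-risk woman takes aspirin with probability 17.4% (dose tag 75 mg
  w.p. 20/75, else 150 mg); each treated would-be preterm-PE case is
  prevented with probability 0.6, independent of dose — the observed
  outcome becomes term PE with delivery redrawn uniformly between 37 weeks
  and the boundary (a relabel-to-no-PE variant is available), while the
  counterfactual outcome is preserved as generator bookkeeping.
- Everything is driven by one seed; identical spec + seed reproduces the
  cohort bit for bit.

Because risks are computed with the same parameters that generate the data,
the posterior is exactly calibrated on unshifted cohorts — a deliberate
self-consistency property used in testing, not evidence that the packaged
defaults describe any real population. What passing tests *do* show:
the engine integrates the stated model correctly (oracle agreement), the QC
stage recovers injected miscentering at realistic n, the aspirin machinery
realizes its stated counterfactual, and the evaluation stack reproduces
textbook ROC behavior. What they *cannot* show: that real biomarkers follow
broken-stick Gaussians with these coefficients, that real risk-factor
dependence matches the additive prior, or that any particular
screen-positive rate (e.g. ~23% under miscentered MoMs) will be observed in
the field — joint covariate structure is not modeled, so cohort-level SPR
is not a calibration target.

## Screening evaluation

- **Aspirin adjustment.** Multiplier `1/(1−effect)` (2.5 at the
  pre-specified effect 0.6). Two conventions: `additive_paper` (default)
  adds `2.5 × (observed treated cases)` as prevented cases — reproducing the
  published worked-example totals (25 observed / 6 treated → 40 total, 34
  high-risk) — while `counterfactual` adds `1.5 ×`, the literal reading of
  the formula (→ 34 total). The two disagree because the source arithmetic
  itself is internally inconsistent; both are first-class.
- **Weighted ROC.** Prevented cases have no observed scores, so each
  observed treated case carries the extra weight implied by the convention
  (weight 3.5 or 2.5); everyone else weighs 1. This keeps the ROC
  well-defined without inventing pseudo-records and reproduces the count
  arithmetic exactly. Cases are observed preterm-PE pregnancies; controls
  are all others. Ties move together (the curve is the empirical step
  function); `sklearn.metrics.roc_curve` computes the curve with
  `drop_intermediate=False`.
- **DR at fixed FPR** uses the conservative step convention: the most
  permissive cutoff whose FPR does not exceed the target, no interpolation.
  Reported cutoffs are displayed as "1:N".
- **AUC** is the trapezoid under the weighted empirical ROC; its 95% CI is a
  stratified percentile bootstrap over women (2,000 replicates by default,
  seeded; weights travel with their owners). The unweighted AUC equals the
  Mann–Whitney statistic, which the tests use as a cross-check.
- **Cohort summary**: mean ± SD with Welch t-tests for continuous
  characteristics, χ² (or Fisher where expected counts < 5) for categorical
  ones, PE vs no PE; one-way ANOVA across {no PE, term PE, preterm PE} for
  the log₁₀ MoMs with Bonferroni correction applied within the marker
  family only. Empty strata yield NA, never an exception.
- **Sample size for AUC** uses the Hanley–McNeil variance with an explicit
  control:case ratio (default 70, roughly an unaffected:preterm ratio at ~1.4%
  incidence): the smallest case count whose SE(AUC) meets the target, with
  the achieved power against a null AUC reported alongside. Published
  sample-size statements of this form do not pin down a unique formula, so
  the function returns its assumptions rather than claiming to reproduce
  any particular published count.

## Pipeline and I/O

`run_pipeline` chains QC → re-centering (factors estimated on unaffected
women, applied cohort-wide) → per-combination risks (history; +MAP; +UtAPI;
+PlGF; +MAP+UtAPI+PlGF; all four) → classification → aspirin-adjusted
performance, and emits a manifest with the SHA-256 hash of the full
configuration and the seed; reruns are byte-identical. Note the *screening*
risks that drive aspirin assignment in the generator are computed on the
observed (possibly miscentered) MoMs — as in a real deployment — while the
evaluation runs on re-centered MoMs.

Cohort CSVs store gestational ages in days (floats; integers accepted),
booleans as 0/1, markers as `*_mom` columns or raw measurements converted
through expected-median models at ingest, and "NA" for missing. Rows
violating the outcome/delivery-age invariants are rejected with line numbers
and logged, never silently dropped; a missing required column is a schema
error naming the column.

## Problem sizes used in the checks

Oracle agreement uses 120 randomized instances on the default grid;
shift-recovery and ordering checks use cohorts of 20,000 (≈250 preterm
cases, the smallest scale at which median-recovery tolerance ±0.02 and the
DR ladder's Monte-Carlo noise are comfortably resolved); incidence
calibration uses 50,000. Bootstrap CIs in tests use reduced replicate counts;
the library default remains 2,000.

## Known limitations

- The default parameters are stand-ins; absolute risks from the packaged
  configuration should not be quoted against any real calculator.
- The prior-likelihood factorization assumes marker deflections depend on
  history only through `g`; real data show residual history–marker
  association that expected-median adjustments absorb only partially.
- Below-grid prior mass uses a frozen-likelihood tail approximation.
- The generator's independent marginals cannot reproduce joint
  characteristic structure (e.g. BMI–hypertension dependence), so
  population-level quantities that depend on it — notably the SPR — are not
  calibrated.
- Term-PE risk modelling, assay calibration, compliance behavior and
  cost-effectiveness are out of scope.
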