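# Methods

## Compartmental model

The simulator tracks person-mass in 640 compartments: sex (2) × five-year
age band (20; band *k* covers ages [5k, 5k+5)) × risk-factor profile (8;
the combinations of obesity, daily smoking and physical inactivity) ×
diabetes status (2). Dynamics are deterministic first-order flows advanced
by forward Euler:

- **Entry** at `entry_rate` persons/year per sex into band 0, factor-free
  and non-diabetic.
- **Aging** as a constant per-capita rate of 1/5 yr⁻¹ (exponential band
  residence); the terminal band 95–99 has no aging outflow.
- **Mortality** per (sex, band, diabetes status); diabetes-neutral by
  default.
- **Risk-factor onset and reversal** move mass between profiles one factor
  at a time at per-(factor, sex, band) rates. Simultaneous two-factor jumps
  are second-order in dt and are not modelled.
- **Diabetes incidence** at hazard λ₀(sex, band) × Π_f RR_f^{factor f
  present}. Relative risks compose multiplicatively, the standard
  proportional-hazards convention for co-occurring exposures. Diabetes is
  absorbing: no remission, and diagnosis status is not modelled.

Migration is not modelled; the open population is entry + mortality only,
and calibration absorbs level effects.

**Numerics.** Default dt = 0.1 yr. A step is rejected if any compartment's
total per-capita outflow rate × dt exceeds 1; under that bound occupancies
provably stay nonnegative. Forward Euler is first-order: the single-cohort
diabetic fraction matches 1 − exp(−λt) with error below λ²t·dt (verified in
the tests, and the error halves as dt halves). With entry and mortality
zero the total population is conserved to 1e-9 relative over hundreds of
steps.

**Calibration.** `calibrate` adjusts a named subset of parameters —
whole-field uniform values (`"baseline_incidence"`), slices (`"onset[0]"`)
or single entries (`"rr[2]"`) — within bounds, minimising the weighted sum
of squared differences between simulated and target prevalences
(scipy `least_squares`, trust-region reflective, started from the supplied
parameters; fully deterministic). More free parameters than targets raises
a warning, not an error. On a three-target synthetic problem the known
generating parameters are recovered to better than 1%.

## Sampling

Individuals are drawn from a state with replacement via one multinomial
over the in-frame strata, probabilities proportional to occupancy. With
replacement is the only coherent choice: compartment occupancies are
continuous masses, not enumerable persons. The default frame is ages 15–79
(13 bands); a band is in frame only if wholly inside the range. Individuals
carry the age band, not an exact age, because the score's age categories
are the bands themselves. Each table records provenance (source time, n,
seed, RNG: numpy PCG64) and round-trips through CSV + JSON sidecar.

## Score derivation

`fit_logistic` fits by Newton–Raphson (statsmodels `Logit`) to gradient
tolerance 1e-8, with dummy coding against fixed references: female, the
youngest band present, factor absent. No interaction terms are ever
included. Complete or quasi-complete separation and non-convergence raise
errors naming the offending covariable. Odds-ratio CIs are Wald intervals
on the β scale, exponentiated.

Points are `round(10·β)` with halves away from zero, applied to the
**full-precision fitted β**, never to a 2-decimal printed value. Published
points tables of this type contain half-integer printed βs whose points are
inconsistent with any rounding of the printed value (e.g. 2.45 → 24 but
1.05 → 11); computing from the unrounded coefficient explains such rows,
so half-integer printed βs are excluded from exact round-trip assertions.
Negative coefficients yield negative points with a warning rather than
silent truncation at zero, which would change the score.

At scale the integer rounding costs little discrimination: the AUC of the
points score stays within ~0.02 of the AUC of the exact linear predictor.

## Evaluation

- **AUC**: tie-corrected Mann–Whitney statistic via midranks, identical to
  the trapezoidal area under the empirical ROC (verified against
  brute-force all-pairs enumeration on hundreds of random tables). CI by
  stratified bootstrap, 2,000 resamples by default, seeded and therefore
  reproducible.
- **Cut-offs**: candidates are the midpoints between adjacent distinct
  observed scores plus ±0.5 beyond the extremes, so integer scores give
  half-integer cut-offs. Flagging rule: score ≥ cut-off. The optimal
  cut-off maximises sensitivity + specificity; ties break toward the
  smallest cut-off (favouring sensitivity, the natural screening
  preference). Constrained variants take the smallest cut-off with
  specificity ≥ s\* (maximising sensitivity subject to it) or the largest
  with sensitivity ≥ s\*; an unattainable bound raises an error stating the
  best achievable value.
- **Proportion CIs**: Wilson score intervals.
- **Predictive values**: PPV = se·p/(se·p + (1−sp)(1−p)),
  NPV = sp(1−p)/(sp(1−p) + (1−se)p), flagged share π = se·p + (1−sp)(1−p);
  p defaults to the sample prevalence. 0/0 cases are reported as NaN
  (not estimable). These identities hold to 1e-12 against the count-based
  definitions on every confusion output.
- **Yields**: per-stratum 1/prevalence. For compartment states the
  stratification is the single-factor grouping conventional in screening
  charts (per sex and band: the obese, the smokers, the inactive, and the
  factor-free); for tables it is any column cross-classification.
  Zero-prevalence strata are flagged not estimable; empty strata are
  skipped with a warning.
- **Comparison harness**: applies several score definitions to one table,
  restricting each to the covariables the table shares and re-optimising
  its cut-off, one row per score.

The bootstrap CI does not correct for cut-off selection (the cut-off is
chosen on the same sample the CI describes); this matches common reporting
practice.

## Synthetic-data generator

`GeneratorSpec` fixes n, the sex split, an age-band distribution over the
15–79 frame, per-factor marginal prevalences (scalar or sex×band), and a
logistic disease model; `generate` draws covariates independently and
disease as Bernoulli(expit(linear predictor)), all from one seeded PCG64
stream. An optional joint 8-profile probability table allows correlated
factors; independence is the default because joint factor distributions
are rarely published.

`builtin_fixture(year)` packages published multivariable models for a
Middle-Eastern national population at 2020, 2030 and 2050 (intercepts
−4.10, −3.95, −3.67; e.g. 2020 obesity β = 1.40 → 14 points) together with
the reported factor marginals (2020: obesity 40.7%, smoking 16.4%,
inactivity 49.3%). Two defaults are this package's own declarations, since
the source tables do not print the sample's composition: a 0.5 sex split
and a uniform age-band distribution. Uniform ages overweight the elderly
relative to a young national age pyramid, so the fixture's diabetes
prevalence (~24% in 2020) and operating points differ moderately from the
published sample's (19.2%); recovery tests therefore target the generating
coefficients, which are known exactly, not the published performance
figures. What passing tests show is that the pipeline is statistically
faithful to its generating model — not that the generator reproduces any
real population's demography, factor correlations, or survey artefacts
(nonresponse, measurement error), which it does not attempt.

## Problem sizes

Parameter-recovery tests use n = 200,000 across five seeds (every fitted β
within 3 SE of its generating value; obesity points exactly 14); marginal
checks use n = 100,000 with 4-SE binomial bands; oracle-equivalence checks
use 100 random tables of n ≤ 500; the end-to-end plausibility check
(AUC in 0.70–0.85) uses n = 20,000 per year. The acceptance script uses
the method's native sample size of 5,000 per year.

## Known limitations

- Forward Euler with one-factor flows; no event-time exactness beyond
  first order. Stiff parameter sets require smaller dt.
- Calibration is local least squares from the user's start; it does not
  search globally and inherits the usual identifiability caveats.
- The generator's independence and uniform-age defaults are statistical
  stand-ins, not demography (see above).
- No survey-design features (weights, clustering), no continuous age, no
  variable selection or regularisation, no calibration-curve or net-benefit
  analysis.
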