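# Methods

This note documents the statistical machinery, the synthetic
data-generating process, the defaults and the numerical choices — what
a maintainer or reviewer needs in order to trust (and distrust) the
right things.

## Estimands and estimators

Two contrasts of 5-year all-cause mortality between initiation
strategies (aromatase inhibitor vs tamoxifen, assignment = first
dispensation):

* **Effect of dispensation (intention-to-treat analogue).** Initiators
  are followed regardless of later adherence, from first fill to the
  first of death, emigration, 60 months, or the administrative end of
  data (default 2015-12-31).
* **Per-protocol effect.** Follow-up is additionally censored at the
  first protocol deviation, and cumulative inverse-probability
  censoring weights correct the selection that censoring induces.

Both use a discrete-time pooled logistic hazard model on person-period
records (1-month clock, 30.4375 days): strategy indicator, restricted
cubic spline of month (knots 6/12/24/36, truncated-power basis,
linear beyond the boundary knots, basis columns scaled by
(t_K − t_1)²), and their product term. Risks come from the
product-limit identity; the strategy coefficient of the no-interaction
model, exponentiated, is reported as the *average hazard ratio by 5
years* — no proportional-hazards claim is attached to it. The 1-month
interval keeps per-interval death probabilities small (~0.2%), which is
what makes the pooled-logistic ≈ proportional-hazards correspondence
accurate; the interval length and knot layout are configurable.

Weighting. Treatment weights are stabilized by default (marginal over
fitted conditional strategy probability, main-effects logistic model on
the full baseline covariate roster; continuous covariates enter with
linear + quadratic terms so location *and* spread differences between
arms can be balanced). Truncation is off by default and available at
symmetric percentiles. A fitted strategy probability of 0 or 1 to
machine precision raises a positivity error rather than silently
producing an extreme weight. Censoring weights are fitted separately
per arm (deviation mechanisms plausibly differ by drug class) on the
at-risk records, with baseline covariates, the eleven time-varying
flags (cerebrovascular disease, diabetes, COPD, cardiovascular disease,
chronic kidney disease, diabetes drugs, anticoagulants, antidepressants,
NSAIDs, opioids, hormone replacement therapy) and the same spline of
time; they are unstabilized by default (the cumulative products stay
modest at realistic deviation rates), with a stabilized option.
Censoring cannot occur in interval 0 (a deviation needs at least one
elapsed interval), so weight products effectively start at j = 1.

Inference is percentile bootstrap over patients (not person-periods);
every model — treatment, censoring, outcome — is re-fitted inside each
replicate, so the intervals carry weight-estimation uncertainty.
Resampling enters as per-patient frequency weights on the pre-expanded
dataset, which is what makes 1000-replicate runs affordable; replicates
whose fits fail are dropped and counted, and more than 10% failures
aborts. Subgroup analyses (age </≥ 65, chemotherapy, opioid-or-
antidepressant use) re-estimate all weight models *within* the
subgroup. Sensitivity variants: (1) baseline covariates in the outcome
model instead of weighting, standardized over the empirical covariate
distribution (g-formula); (2) complete-case analysis dropping any
patient with a "missing" category.

## Exposure episodes

A fill supplies `pills × strength / DDD` days (WHO defined daily doses:
letrozole 2.5 mg, anastrozole 1 mg, exemestane 25 mg, tamoxifen 20 mg;
shipped as an editable table), rounded to whole days, minimum one.
Unused supply carries forward: a same-class fill extends coverage from
the later of its date and the current supply end (standard stockpiling
convention). `covered_until` marks the first uncovered day. Treatment
is continuous while gaps stay under 60 days; the deviation date of a
gap is `covered_until + 59` — the day the 60-day gap is confirmed — and
of a switch, the other-class fill date. With no further fills, the gap
deviation is declared only if the grace period elapses before follow-up
ends. Whether the real analysis measured the gap from end-of-supply or
from the previous fill date is not documented anywhere we could verify;
end-of-supply is implemented and flagged as a choice. Discontinuation
for contraindication is indistinguishable from any other stop in
dispensation data, so every stop counts as a deviation; this is a
fidelity limit of the design, not of the code.

## Eligibility and covariates

Criteria are applied in a fixed order, each recording its removals
(women ≥ 40; postmenopausal proxy: age ≥ 50 at diagnosis or an optional
flag column; hormone-receptor-positive; stage 1–3; surgery with clear
margins; first endocrine dispensation within 274 days — a documented
whole-day rendering of "9 months" — after surgery and inside the
2009-08-01..2015-12-31 window; no history exclusion flags; unambiguous
first fill). Same-day first fills of both classes make assignment
undefined and exclude the patient. Comorbidity flags use all recorded
history up to baseline; co-medication flags use a 6-month lookback
(both configurable — the source analyses cite supplementary definitions
that are not reproducible here). Missing categoricals become an
explicit "missing" level; nothing downstream ever sees an absent value.

Person-time: death is assigned to the interval containing the death
date; the partial interval at the administrative end is kept (that is
how a registry extract truncates), the partial interval at emigration
is dropped; death and deviation in the same interval count the death.

## The synthetic registry

The generator emulates the joint structure the estimators assume, not
breast-cancer biology (only all-cause death is generated; no
recurrence, no cause of death).

* **Covariates.** A two-component latent-profile mixture: a latent
  class with mixture weight equal to the observed treated fraction
  (0.641), and, given the class, each covariate drawn independently
  from its arm-specific published marginal (counts shipped in
  `emutrial.calibration`). Age is truncated-normal and
  time-from-diagnosis log-normal per class, matched to the published
  medians and IQRs. An optional Gaussian-copula equicorrelation knob
  adds within-class dependence among comorbidity/co-medication flags
  (marginals preserved); its default is 0 because no dependence
  structure is published — the latent class itself already induces
  realistic positive dependence.
* **Treatment choice.** A logistic model on the covariates. The default
  coefficients are the exact log-likelihood-ratio (naive-Bayes dual)
  coefficients of the mixture, with the intercept solved in-sample to
  hit the treated fraction; then P(A|X) equals the posterior of the
  latent class and the arm-conditional covariate distributions
  reproduce the published table in expectation (e.g. chemotherapy
  30.3% vs 6.0%). Setting coefficients to zero removes confounding;
  the continuous covariates carry linear + quadratic terms because the
  log-ratio of two normals with unequal variances is quadratic.
* **Death.** Per-interval logistic hazard on baseline covariates plus
  `true_treatment_log_or` while an aromatase inhibitor is actually
  taken (off-treatment and tamoxifen intervals sit at the reference
  level, making the configured log odds ratio exactly the conditional
  AI-vs-tamoxifen contrast under sustained use). Default effect
  log(0.91) and baseline hazard −7.5 logits at the reference profile,
  chosen so marginal 5-year mortality lands near the published 10–13%
  band. Optional effect-modifier coefficients add covariate-dependent
  effects for subgroup validation.
* **Dispensations.** First fill at baseline (AI patients split
  letrozole/anastrozole/exemestane 55/35/10; a fifth of tamoxifen fills
  use 10 mg tablets at two per day); supplies of 30/90/100 days;
  refills mostly early, occasionally up to 59 days late (so adherent
  streams never breach the grace rule, and no refill before day 31, so
  deviations always fall after interval 0); per-interval
  discontinuation hazard per arm (default ~0.9%/month, giving the
  published ~58% five-year persistence), optionally covariate-dependent;
  a stopped patient switches to the other class at the next scheduled
  fill with probability 0.3. Streams truncate at death/emigration.
* **Histories.** Prevalent comorbidities get onset dates before
  baseline and prevalent co-medication a fill inside the lookback;
  post-baseline onsets and fills arrive at small monthly rates to
  exercise the time-varying machinery. Small independent fractions of
  records deliberately fail single eligibility criteria so the
  exclusion flowchart is non-trivial; independence keeps the eligible
  subset's distribution equal to the calibration target.
* **Truth oracle.** Under sustained treatment the conditional monthly
  hazard is constant, so each patient's counterfactual 5-year risk is
  exactly 1 − (1 − p_a(L))⁶⁰. The oracle draws a fresh population,
  applies the eligibility filter, and averages the exact per-patient
  risks — the only Monte-Carlo error is population sampling, reported
  as a standard error that shrinks like 1/√n.

**What passing tests do and do not show.** The generator's missingness
is category-level (arm-specific rates, at random given arm), its
covariate dependence comes from one latent dimension, and its hazards
are time-constant given covariates; real registry data have richer
dependence, informative missingness, and duration effects. Recovery of
truth here validates the estimation machinery, not the causal
assumptions in any real dataset.

**Calendar censoring.** Under the default scenario the two arms enroll
on very different calendar schedules (as published), so administrative
censoring at the end of data is differential by arm and correlated with
case mix; the weighted estimate then differs from the sustained-use
truth even with every baseline confounder measured. This is a property
of the design being emulated, not a bug; the `recovery.yml` scenario
(short enrollment window, full adherence, stated moderate confounding
coefficients) exists precisely to benchmark the weighting machinery
without that distortion, and the bootstrap-calibration scenario
(`coverage.yml`) is its n = 2000 variant.

## Numerical choices

* All logistic fits (treatment, censoring, outcome) use one in-package
  Newton–Raphson/IRLS solver with step halving; convergence on
  parameter change (10⁻¹⁰) or deviance plateau — the latter terminates
  quasi-separated fits whose drifting coefficients leave fitted
  probabilities (all the weights use) stable. The solver accepts
  fractional responses with trial weights, so the marginal outcome
  model is fitted on person-periods aggregated by (strategy, interval)
  cells — identical estimates, two orders of magnitude faster inside
  the bootstrap. statsmodels reproduces its coefficients to 10⁻⁶ in the
  test suite; it is deliberately not the implementation so that it can
  serve as an independent check.
* A "saturated" time basis (free hazard per strategy-interval cell) is
  provided; its risk curve is exactly the weighted Kaplan-Meier
  estimate, used as an oracle in tests.
* Boundary knots: 6 and 36 months are treated as the boundary knots of
  the restricted basis (linearity outside [6, 36]); the alternative —
  anchoring the boundary at the data range 0–60 — would need different
  basis constants and is not what a knots-at-6/12/24/36 specification
  conventionally means.
* Ties and degenerate inputs: death wins over same-interval deviation;
  a deviation index beyond observed follow-up is ignored; an empty fill
  list is an error (assignment requires a fill); zero-event arms raise
  a diagnostic error for the spline model (a saturated arm without
  events is legitimately hazard 0); a tamoxifen risk of exactly 0 makes
  the risk ratio undefined and is reported as absent with a warning.
* Determinism: every stochastic step draws from
  `numpy.random.default_rng` streams spawned from a single seed; the
  same seed and configuration give byte-identical tables and reports.

## Problem sizes used by the shipped validation runs

Parameter recovery uses 10 replicate cohorts of n = 20 000 under
`recovery.yml` against a 200 000-draw truth oracle; bootstrap coverage
uses 200 cohorts of n = 2 000 with 200 replicates each; the oracle
equivalences run on ≤ 50-patient cohorts and 1 000 random fill streams.
`scripts/acceptance.py` runs the default scenario at its published size
(n = 12 536) with 200 (intention-to-treat) and 100 (per-protocol)
bootstrap replicates. These sizes give Monte-Carlo error comfortably
inside the asserted tolerances while keeping a full run on one core in
minutes.

## Known limitations

* The per-protocol machinery treats all stops as deviations; allowed
  contraindication-driven discontinuation is not modelled (not
  identifiable from dispensations).
* IPCW validity rests on the censoring model covering the deviation
  mechanism; the generator's optional covariate-dependent deviation
  uses baseline covariates, which the model includes, but real
  mechanisms may depend on unmeasured or post-baseline variables.
* The average hazard ratio is a weighted summary over 60 months; under
  strong non-proportionality it has no single-period interpretation.
* Subgroup inference reports estimates only; no interaction tests.
* Joint analysis with external randomized-trial data (transportability)
  is out of scope.
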