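# Methods

## Problem and scope

`opiphen` implements an algorithm-development procedure for computable
phenotyping of clinically documented problem prescription opioid use among
long-term ER/LA opioid recipients, using only structured claims-style
inputs: demographics, enrollment spans, encounters, diagnoses, procedures,
and pharmacy dispensings in a simplified Sentinel-CDM-like layout, plus a
reference-standard label table (problem-use status and documented onset
date, as produced by protocolized chart review). The package covers the
full chain — cohort construction, enriched sampling with design weights,
predictor operationalization, adaptive-LASSO model fitting, and
cut-point-based evaluation — together with a synthetic data generator that
stands in for the (unavailable) source data.

## Synthetic claims generator

The generator is a documented set of assumptions, not a calibration to any
health system. Its skeleton:

* **Enrollment** — one span per patient with uniform start/end inside the
  study period (2006-01-01 .. 2015-06-30 by default); with hazard 0.15 a
  span is split by a gap (geometric length, mean 45 days), exercising the
  continuous-enrollment filter.
* **ER/LA therapy** — 75% of patients receive a refill renewal process:
  next fill = previous + days' supply (28/30/90-day categorical choices)
  plus small Poisson lateness, with probability `early_refill_prob` (0.12
  base) of an *early* refill at 50–85% of the supply interval, which
  creates overlapping coverage. Total regimen length is log-normal
  (median ≈ 1,100 days, σ = 0.9), roughly matching the long-term use the
  cohort definition targets.
* **Other streams** — IR opioid, benzodiazepine, other-psychoactive and
  background fills, diagnoses (pain, mental-health, comorbidity, misc,
  and opioid dependence/abuse/poisoning codes), encounters (outpatient,
  ER) and procedures (urine drug screens, SUD treatment, surgery) are
  piecewise-constant-rate Poisson processes within enrollment; defaults
  are in `StreamRates` with units per month or per year.
* **Latent trait** — a Bernoulli(0.25) problem-use trait multiplies stream
  intensities via `EffectProfile` (early refills ×2.5, dose ×1.8, ER
  visits ×2, benzodiazepine co-dispensing ×2.5, OUD-treatment medication
  ×10). The opioid-diagnosis hazard rises ×8 after a latent onset drawn
  near the regimen start; the *documented* onset lags it by a geometric
  delay (mean 60 days), so positives can have onsets before, inside, or
  after any downstream observation window. The default profile is
  deliberately strong: it gives the downstream model a clearly learnable
  signal, which is what the pipeline's guarantees are stated against.
* **Dose** — each product carries mg-per-unit and a CDC-style
  morphine-equivalence factor (`codes.DRUG_CATALOG`); the source method
  publishes no conversion table, so these are package defaults.

What the generator does **not** emulate: real code-frequency distributions,
provider/site effects, seasonality, death or disenrollment tied to health
state, channeling between IR and ER/LA therapy, and measurement error in
days' supply. Passing tests therefore demonstrate correctness of the
pipeline's mechanics and its statistical procedures under a known
generative model — not expected performance on real claims, where the
published experience is that even the full procedure falls short of
gold-standard accuracy.

One deliberate omission: the generator never emits tobacco-use-disorder
codes (305.1x), which in real ICD-9 data fall inside the conventional
`304.*/305.*` comparator prefix set. Keeping them out of the synthetic
streams keeps the comparator and the enrichment stratum opioid-specific
without narrowing the printed code list itself.

## Cohort rules

* **Index date** — the first ER/LA fill `d` whose closed 90-day window
  `[d, d+89]` accumulates ≥ 60 days' supply *dispensed* in the window
  (coverage-day attribution is not used; the buprenorphine product class
  is OUD-treatment, never ER/LA, so it cannot qualify). Candidate windows
  are anchored at fill dates; a brute-force daily-grid oracle in the test
  suite confirms anchor equivalence for the returned index.
* **Enrollment** — a single span (after bridging gaps ≤ a configurable
  tolerance, default 0 days) must cover index −6 through +18 calendar
  months. Month arithmetic uses calendar offsets with end-of-month
  clamping.
* **Encounter quarters** — ≥ 8 distinct calendar quarters with any
  encounter.
* **Observation window** — index −12 months through +24 months minus one
  day (36 months). The outcome is positive iff the documented onset is on
  or before the window end; onsets *before* the window count as positive.

## Sampling and design weights

Strata are the cross of age at index (18–34 vs 35+) with any qualifying
opioid dependence/abuse/poisoning code (965.01 heroin poisoning excluded)
during the study period. The default design takes both enrichment strata
in full and samples the base stratum at the fraction reaching the target
size. Selection probabilities are the realized k/N per stratum, so
design weights 1/p make the weighted prevalence estimator exactly
Horvitz–Thompson; weights are used **only** for prevalence estimation,
never in model fitting. The 70/30 split uses exact sizes round(n·f).

## Predictor catalog

The shipped library (`default_spec_library`, 109 specs) covers every
builder family: diagnosis flags/counts/percent-of-quarters over the code
groups, a distinct-pain-site count, days'-supply and fill-count aggregates
by drug class and calendar grain, MEQ summaries (mean/max daily, dose per
supplied day, days above {50, 90, 120} MEQ/day, percent of quarters above
threshold, consecutive-quarter rises ≥ {33, 50, 75}%), overlapping-fill
patterns (including the canonical "≥3 partially overlapping IR fills of
≤14 days' supply dispensed Saturday/Sunday/Monday within 3 months"),
opioid–psychoactive concomitancy day counts, ER encounters during opioid
coverage / overlap / high-MEQ days / same-day fills, urine-drug-screen
counts and proximity (±7 days) to overlap or high-MEQ days, OUD-treatment
medication measures, a simplified 17-category Charlson index,
demographics, and age-group interaction products. The catalog is a
curated, documented subset spanning every category rather than a
reconstruction of any specific site's 1,126 operationalizations; counts
are configuration, not contract.

Conventions: a fill covers the closed interval `[dispense_date,
dispense_date + days_supply − 1]`; daily MEQ is `quantity × mg_per_unit ×
meq_factor / days_supply` summed over covering fills; calendar month and
quarter grains are clipped to the window, partial quarters counting as
quarters; the rolling span for overlap chains uses 30.4375-day months.
"High MEQ" thresholds default to {50, 90, 120} MEQ/day — the method names
high-dose variants without values, so these are package defaults. The RR
screen dichotomizes non-binary predictors at "any nonzero" unless an
explicit cut is supplied, and flags zero-denominator ratios undefined
rather than infinite.

## Adaptive LASSO

Objective: `−loglik + λ Σ_j w_j |β_j|`, intercept unpenalized, with
`w_j = 1/max(|β̂_ridge,j|, 1e−6)^γ` from an L2 fit (penalty `α/2·||β||²`,
α = 1 by default) on the standardized training predictors. Predictors are
standardized to unit variance before penalization and coefficients mapped
back to the original scale.

* **Solver** — cyclic coordinate descent with soft-thresholding on the
  IRLS quadratic approximation (glmnet-style), IRLS weights floored at
  1e−6, convergence when the largest parameter update falls below the
  tolerance (1e−8 standardized). Zeros are exact by construction. The
  test suite verifies the objective against an independent convex solver
  (saga on weight-rescaled columns, which solves the identical problem)
  to ≤1e−6 relative error, and the λ=0 / λ→∞ limits against the
  unpenalized MLE and the intercept-only model.
* **Grids** — γ ∈ {0.5, 1, 2}; λ descends geometrically from λ_max (the
  smallest value zeroing every coefficient at the null model) over 30
  points spanning three decades, fitted with warm starts. A denser
  50-point/four-decade path is one configuration call away; the default
  keeps the 8-fold × 3-γ cross-validation of a 1,400 × 100+ problem
  around ten seconds without visibly moving the selected pair.
* **Cross-validation** — folds are stratified by outcome (an unstratified
  scheme risks event-free folds, which the code rejects with a
  diagnostic) and seeded. Ridge weights are re-estimated inside each
  training fold; the held-out loss is Σ(y−p̂)² on the probability scale.
  Ties prefer the larger λ, then the smaller γ.
* The post-selection "selected interactions among retained terms" refit
  step is not implemented: no selection rule is specified for it, so the
  model stops at the cross-validated adaptive-LASSO fit.

## Evaluation

Classification is "risk score at or above the cut"; ROC tie handling
follows the same rule. For target-metric schemes the chosen cut is the one
meeting the target on training data while maximizing the complementary
metric (PPV for sensitivity targets, sensitivity otherwise) — an
interpretation of "optimize performance at a desirable level" — with ties
to the higher cut; the balanced scheme minimizes |sensitivity − PPV|.
Undefined metrics (0/0) surface as None/NaN, never 0 or 1. The comparator
classifies positive on any qualifying diagnosis code inside the
observation window. In the end-to-end check, "the model beats the
comparator" means validation AUC exceeds the area under the single-point
ROC through the comparator's operating point, i.e. its balanced accuracy
(sens + spec)/2. The binomial CI helper is Wald by default (exact
Clopper–Pearson by flag), reported in percent and rounded to whole
percent for display.

## Problem sizes

The shipped tests and `scripts/acceptance.py` run the pipeline at 2,000
simulated patients (≈1,350 eligible after filters), the support-recovery
study at n=1,400 × p=100 with 8 true standardized effects of |β| ≥ 0.5
over 20 replicates, the solver-oracle comparison on 20 problems of up to
200 × 10, the brute-force cohort oracles on 1,000 random record sets
each, and the design-weight study on 500 stratified draws from a
4,000-patient pool — sizes chosen to exercise each guarantee at the scale
of the study design it mirrors.

## Known limitations

* Generator realism as listed above; in particular prevalence-linked
  enrollment and IR→ER/LA channeling are absent, so the
  prevalent-user-cohort complications discussed in the source literature
  do not arise in simulation. The prevalent-vs-incident-user distinction
  is noted here but not implemented as a filter.
* The dichotomization cut-points for continuous predictors in the RR
  screen, the high-MEQ thresholds, and the interaction choices are
  package defaults labelled as assumptions.
* Whether the 60 days' supply must come from overlapping coverage or
  merely be dispensed within the 90-day span is ambiguous in the source
  definition; the dispensed-within-span reading is implemented.
* Variance estimation for the weighted prevalence (beyond the binomial CI
  helper) is out of scope.
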