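# Methods

This note documents the models, conventions and design choices behind
`healthscopes`, in the order the pipeline runs them.

## Records and exclusions

Inputs are four UTF-8 CSV tables (persons, conditions, programs,
encounters) with ISO-8601 dates; death registrations are folded into
`persons.death_date`. The base population for an index year retains
persons with known ethnicity, age at most 110, and alive at some point in
the year. Removals are attributed to the *first* matching reason in the
fixed order ethnicity-missing → age > 110 → not-alive-in-year, so the
exclusion counts partition the removals and are reproducible regardless of
how many criteria a person trips. Age is `year − birth_year` ("age attained
in the year"); birth dates at day granularity are not assumed. The age-110
cutoff treats implausibly old records as missing death registrations.

Person-year features use two windows: program flags (nursing-home
admission → frailty, palliative referral, transitional-care enrollment)
count only events dated inside the index year, while condition history is
cumulative — any registry diagnosis dated on or before Dec 31 of the index
year counts, with no wash-out, because chronic-disease registries record
first diagnoses that remain clinically relevant indefinitely.

## Condition registry and chronic-state flags

The registry maps each condition code to one category: simple chronic,
complex chronic (requires specialist care), mental health, cancer, or
obesity. `n_chronic` counts *distinct* non-obesity registry conditions,
including mental-health and cancer codes — this is what routes a child with
cancer (and no transitional needs) into the pediatric chronic segment,
since the cancer and mental-health segments are defined for adults and
seniors only. A person is complex-chronic if they carry ≥ 2 distinct
conditions or any single specialist-care condition; simple-chronic means
exactly one condition, of the simple category. Obesity (historical BMI ≥
27.5 kg/m², the Asian-population cutoff) is a risk factor, never a chronic
condition.

## Classification hierarchy

The default precedence `L, K, I, J, H, G, D, F, E, C, B, A` orders rules
from highest to lowest healthcare need; classification is first-match and
total (the mostly-healthy rule is a catch-all). The full rule list,
internal branch criteria and age-band cutoffs are configurable
(`CriteriaConfig`), with defaults reproducing the canonical hierarchy.
Choices that were genuinely open:

* **End of life** is operationalized as death *during* the index year or a
  palliative referral during it. The alternative lookahead definition
  (death within 12 months after the index year) is supported behind
  `eol_lookahead`, default off, because it cannot be evaluated in real time.
* **Children with cancer or mental-health conditions** route to the
  pediatric transitional segment if they have transitional needs, else to
  the pediatric chronic segment — a convention, since the cancer and
  mental-health segments are adult/senior by definition.
* **Broad-group membership of the pediatric transitional segment**: counted
  under Getting Well in all aggregate tables and analyses.

Percentages in the size and demographics tables round half-up to one
decimal; age dispersion uses the sample SD (n − 1). These display
conventions matter when checking table arithmetic exactly.

## Synthetic generator

The generator emulates the structure of a linked national extract under
explicit study conditions:

* **Mixture**: latent segments are drawn from the published national
  segment shares (mostly-healthy ≈ 63.7% down to pediatric-transitional ≈
  0.1%). Default population size is 50,000 — small enough to run anywhere,
  large enough that every segment is populated.
* **Demographics**: per-segment age (truncated normal within the segment's
  permissible band), gender, ethnicity, housing, financial-assistance tier,
  obesity history and living-alone status, anchored to the published
  per-segment demographics. At-risk segments are guaranteed ≥ 1 risk
  factor (defaulting to the high-subsidy tier when none is drawn); the
  healthy segment has zero mass on every risk factor, matching the
  published table's zeros, which are themselves artefacts of the criteria.
* **Strict mode** (default): records deterministically satisfy exactly the
  latent segment's rule and no higher-precedence rule, so classification
  recovers the latent labels for 100% of persons. One consequence: only
  end-of-life persons die in the index year (any other in-year death would
  reclassify the person end-of-life). The index-year death share within
  that segment is 0.54, taken from the published ratio of the segment's
  validation-cohort size to its index size. Non-strict mode draws a
  configurable fraction of persons' features from an adjacent need tier.
* **Index-year encounters**: per segment × setting hurdle (use
  probability, then 1 + Poisson positive counts), lognormal charges
  (σ = 0.7) with per-setting medians scaled by a per-segment severity
  multiplier. Charge levels are calibrated *only* so that mean
  per-resident charges rank the transitional, end-of-life, frail and cancer
  segments far above the healthy tiers; real dollar levels are out of
  scope.
* **Follow-up outcomes**: visit counts are Poisson with mean
  `segment rate × exposure`, where exposure is the fraction of the
  follow-up year alive and the per-segment rates equal a baseline
  mostly-healthy rate plus the published per-segment marginal effects —
  so the generator's true contrasts are the published effect sizes. Bed
  days accumulate per admission. Deaths are per-segment Bernoulli with
  uniform death day; probabilities grade steeply across tiers so the
  broad-group hazard ordering (maximizing > getting > living > staying)
  is resolvable at synthetic sample sizes. ICU probabilities follow the
  published odds-ratio grading with the frail/end-of-life tier lifted
  (0.09 / 0.30): the published broad-group gap there (27.84 vs 27.13) is
  far below Monte-Carlo resolution at 50,000 persons, and the generator's
  job is to encode the qualitative ordering. The ICU flag is drawn
  independently of the admission count — a simplification; real ICU stays
  imply admissions.

What passing tests therefore establish: the classifier, tabulations and
estimators are correct on data whose generating process is fully known.
What they do not establish: performance under miscoded records, informative
missingness, private-sector utilization gaps, or real charge distributions —
none of which the generator models.

## Validation models

The cohort is persons segmented in the index year and alive at its end;
follow-up-year decedents contribute exposure `death day / 365` (day-count
exposure was chosen over person-months; the scale cancels in group
contrasts). Log exposure enters both parts of the two-part model as an
offset by default — the single published offset is placed in both the
any-use and positive-use equations, with `offset_parts="part2"` restricting
it to the continuous part for sensitivity checks.

* Part 1 is a logit-link binomial GLM of any use; when every outcome is
  positive the hurdle collapses and `P(use) ≡ 1` is used directly.
* Part 2 is a log-link GLM of positive use. Family selection fits Poisson,
  Gamma, negative binomial and Gaussian and keeps the AIC minimizer (ties
  break in candidate order). AIC is also reported per observation, the
  scale on which such analyses conventionally print it. Negative-binomial
  dispersion is estimated by maximum likelihood jointly with the
  coefficients (NB2).
* Marginal effects average, over the cohort's observed exposures, the
  difference in predicted outcome between membership in `g` and in the
  reference; the reference's effect is identically zero. CIs resample
  persons (percentile bootstrap, B = 500 default, seeded). For saturated
  group-only designs at unit exposure with Poisson/Gamma/NB families, the
  per-resample MLE group means equal the resample's sample means, so
  bootstrap refits are computed in closed form; a test verifies the fast
  path equals full GLM refits on shared resamples. A numeric-gradient
  delta method is available as an alternative.
* Groups with zero positive outcomes are flagged nonestimable (part 2
  cannot be fit for them) rather than failing the whole model; the same
  convention applies to all-0/all-1 groups in the ICU logistic model and
  zero-death groups in the Cox model.
* The Cox model uses Efron tie handling on day-scale durations censored at
  365. Reference groups: staying-healthy / mostly-healthy for utilization
  and ICU models; living-well / simple-chronic for survival, where deaths
  are frequent enough to be informative. Child-only segments are dropped
  from segment-level survival by default (deaths too rare). Because the
  hazard contrasts can exceed e⁴, the Newton solver is run over a small
  ladder of step sizes and the solution with the highest partial
  log-likelihood is kept; on reference data this reproduces the R
  `survival` fit to full precision.

## Numerical conventions and degenerate inputs

Empty inputs yield empty outputs throughout (classification of an empty
table, charge summaries with no encounters). Zero-resident segments report
zero totals and undefined percentages. Mean-per-resident × resident-count
equals total charges to 1e-9 relative. All randomness flows from a master
seed through named child streams (population, follow-up, bootstrap), so a
pipeline rerun with the same config reproduces byte-identical outputs.

## Known ambiguity

The source analyses report two slightly different 2016 segmented counts
(4,671,465 in the size table vs 4,701,074 in the validation section)
without explanation. This package exposes a single base population; the
size-table figure is the one its arithmetic checks reproduce.

## Problem sizes

Default test and acceptance runs use: 50,000-person populations for
round-trip and ordering checks; n = 20,000 for marginal-effect recovery;
500 replicates of n = 2,000 (B = 400) for bootstrap coverage; 100
replicates of n = 2,000 for family selection; 5,000 per group for Cox
recovery. These sizes put Monte-Carlo error well inside the assertion
tolerances while keeping a full run in minutes.
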