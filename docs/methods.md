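# Methods

This note documents the models, rules and numerical choices behind
`sdvimpact`: what the synthetic cohort emulates, how errors and corrections
are modelled, how the audit engine classifies discrepancies, how the
analysis variables and time-to-event estimates are computed, and where the
open design choices were settled.

## The problem being modelled

Multi-site observational HIV cohorts pool routinely collected clinical data.
Source data verification (SDV) audits compare the research database against
original source documents (charts, lab reports) for a random sample of
records, code every field, and feed findings back to sites. Two years later
a revised submission round produces a corrected database. The question the
pipeline answers is: *how much do data errors — and their correction — move
the epidemiologic estimates a cohort would actually publish* (cumulative
incidence of death and AIDS after ART initiation; adjusted cause-specific
hazard ratios)?

Because real multi-site HIV data cannot be redistributed, the package
simulates the entire process with a known gold standard ("truth"), so every
downstream statistic has an exact oracle.

## Data model

Five delimited tables in a HICDEP-like layout: `patients`, `visits`, `labs`,
`art`, `events`, plus a YAML manifest carrying the version label and
per-site freeze dates. Dates are ISO 8601 on disk; all date arithmetic is in
whole days.

The variable registry holds 23 entries partitioned 19 / 2 / 2: nineteen
primary variables collected in all three dataset versions, two (CDC and WHO
stage at enrollment) collected pre-audit and at audit only, and two
replacements (clinical AIDS indicator, AIDS diagnosis date) collected only
in the post-audit round — so each version exposes exactly 21 variables. The
exact source variable list is not public; this registry is a reconstruction
covering every variable the analyses need (demographics, enrollment, visit
dates and weights, CD4 and viral-load values/dates, ART regimen and
start/end dates, clinical event codes/dates, vital status). `weight` and
`death_cause` are included as routine transfer-protocol variables to
complete the 19 common slots; neither feeds the derived variables.

Child-table rows carry a stable `row_uid`. Real audits track specific
records through audit forms, so record identity survives the error process;
the audit engine aligns on `row_uid` when both sides have it and falls back
to greedy nearest-date matching (30-day tolerance, ties broken by value
agreement) otherwise. The uid path is what makes the log-equivalence oracle
exact; the date path is exercised separately.

## Synthetic cohort

Nine sites in seven Latin American countries (Argentina and Honduras
contribute two sites each), enrollment uniform over 1996–2013, staggered
site freeze dates in 2014. Defaults:

| parameter | default | rationale |
|---|---|---|
| patients/site (study preset) | 2,780 × scale | yields ≈19–20k pre-audit adults at scale 1 after ≈14% of truth records are absent from the submission |
| proportion under 18 | 0.10 | paediatric records excluded downstream |
| ART initiation probability | 0.92 | late-but-near-universal initiation era |
| baseline CD4 | log-normal, median 150 cells/µL, log-sd 0.9 | late-initiation setting; free parameter, not a claim |
| visit interval | 90 ± 21 days | quarterly clinic schedule |
| dropout hazard | 0.07 / person-year | plausible attrition |
| death / AIDS baseline rates | 0.022, 0.055 / person-year | give ≈7% 3-year mortality and ≈13–18% 3-year AIDS at reference covariates |

Death and AIDS latent times are exponential draws from independent
cause-specific proportional-hazards models; the first event is observed and
the competing event acts as censoring. Log-hazard coefficients cover age
(per decade), sex, IVDU, baseline clinical AIDS, log2 baseline CD4, regimen
class, and a smooth U-shaped calendar-year effect (so spline terms in the
analysis model are non-trivially exercised). Every patient receives a
closing visit at the exact end of follow-up, which makes
`min(freeze, last contact)` censoring reproduce the latent follow-up time
exactly — the TruthLog therefore serves as an exact oracle for the
derivation stage, not an approximation.

An AIDS event drawn within the 7-day baseline grace window is reclassified
as history (both in the generated tables and in the TruthLog), mirroring the
derivation rule, so generator and derivation agree by construction.

What the generator does **not** emulate: the real cohort's covariate joint
distribution, site-level case-mix differences beyond random variation,
informative censoring, measurement drift, or within-patient correlation of
errors. Passing tests therefore demonstrate the correctness of the
machinery and the direction/magnitude of error-propagation mechanisms, not
numeric agreement with any real cohort's estimates.

## Error and correction processes

Field errors are independent Bernoulli draws per occurrence: `make_missing`
or `corrupt_value`, with per-variable rates. Corruptions are kind-specific:
dates get a ±1–60-day shift, a day/month transposition (when it yields a
valid, different date) or a ±1/±10-year typo; categoricals draw a different
level (or follow a configured confusion matrix); numerics get order-of-
magnitude or additive typos; strings swap against another observed value.
Declared systematic site effects (e.g. a month/day swap of one variable at
one site) are deterministic — the two regimes real audits distinguish:
isolated typos vs. systematic misinterpretation. Record-level operations
drop patients or visits, duplicate patients, and insert unregistered
patients. Every change is logged one row per field (record ops one row per
record), and the log is complete: truth vs pre-audit differences and log
rows correspond one-to-one.

Unverifiability is modelled as a property of the *audit*, not of the stored
value: during audited-dataset construction each field of a completed record
is independently skipped (probability 1 − audited_fraction, default 0.75),
marked unverifiable (per-variable rate), or set to the truth value. Records
selected but not completed (completion rate 0.79 of a 35-per-site stratified
sample) contribute nothing.

The correction model fixes each logged error with probability
`correction_probability` (per-variable), enters missing child rows
(`backlog_entry_probability`) and previously missing patients
(`newly_added_patient_rate`, only those enrolled before their site's freeze
date), removes duplicates/unregistered records, and optionally leaves
residual errors. Finally every data point after the site freeze date is
truncated so pre- and post-audit cover the same window.

Preset rates were chosen once so the *expected* audited-subset profile
matches the study conditions: overall discrepancy ≈17%, discrepancy mix
≈43% missing / 34% conflicting / 23% unverifiable, low rates for enrollment
demographics (sex ≈1%, birth date ≈4%), high rates for clinical event dates
(≈49%) and ART end dates (≈31%), ≈14% of truth records absent pre-audit,
and ≈75% of fields audited. These are expectations, not hard constraints.

A boundary effect worth knowing: if a corrupted date moves a record past the
freeze date and is not corrected, truncation removes the record (or nulls
the death fields), which can *lower* a variable's post-audit agreement with
truth even though corrections only ever move values toward truth. The
monotone-quality property (post ≥ pre agreement per variable) is exact when
corruption cannot cross the freeze boundary, and is tested under that
condition.

## Audit engine

Codes follow the standard SDV scheme: A1 match; A2 minor discrepancy; A3
major discrepancy; A4 value in source but never entered in the database; A5
unverifiable (overrides the value comparison). The minor/major split is not
externally defined; defaults are ≤30 days for dates and ≤5% relative for
numerics (any categorical change is major). The split does not affect
discrepancy rates — a discrepancy is any missing, conflicting (A2∪A3) or
unverifiable field — so it is a reporting refinement only. Fields outside
the audited mask are `not_audited` and excluded from denominators; a
database value absent from the source is a missing-category discrepancy
with its direction recorded. Rates are reported with raw counts always
retained; the overall audited-subset rate is conventionally printed to one
decimal percent, per-variable rates as integer percents.

## Derived variables and inclusion

All clocks anchor at ART initiation (earliest recorded regimen start).
Patients are excluded if they never initiated ART or were under 18 at
initiation (an ART start before birth is a logged data defect, excluded via
the age rule). Rules, each configurable:

* **Baseline CD4** — default *nadir*: minimum CD4 at or before initiation
  (the convention used when reporting "nadir CD4" covariates); alternative:
  nearest measurement within [−180, +7] days, ties toward the pre-initiation
  side.
* **Baseline clinical AIDS** — enrollment AIDS flag, or any AIDS-defining
  event dated ≤ initiation + 7 days (unbounded lookback). Incident AIDS
  requires an event strictly after that grace window, so one event cannot
  count as both history and outcome.
* **Censoring** — min(site freeze date, last recorded visit/lab contact).
* **Regimen class** — drug-string lookup to {NNRTI, boosted PI, other}.
* Sites are pooled within country into a single analysis site.

Fourteen derived variables (analysis site, age at ART, sex, IVDU, baseline
AIDS, baseline CD4, regimen class, initiation date and year, the two
time/indicator pairs, and the inclusion flag) are compared across versions
over the union of patients; differing or one-sided-missing values are
discrepant.

## Survival estimators

* **Kaplan–Meier** product-limit with Greenwood variance and log–log 95%
  intervals. Cross-checked in the tests against an exact rational-arithmetic
  product for n ≤ 20, lifelines, and the exponential closed form at n=20,000.
* **Cumulative incidence** is 1 − KM per endpoint, i.e. cause-specific
  censoring of the competing event — consistent with reporting
  "cause-specific hazard ratios". (At the event rates simulated here the
  difference from an Aalen–Johansen estimator is small; the 1 − KM choice is
  recorded in every report's notes.)
* **Restricted cubic splines** in the truncated-power form: linear term plus
  k − 2 restricted cubic terms normalised by (t_k − t_1)², linear beyond the
  boundary knots; 4 knots at the 5/35/65/95th percentiles (the standard
  default). Linearity beyond the boundary knots is verified to 1e−8 by
  finite differences.
* **Cox model**: stratified partial likelihood (strata = analysis site),
  Efron tie handling by default (Breslow available), maximised by
  Newton–Raphson with step-halving from β = 0. Convergence when the maximum
  absolute gradient falls below 1e−6, capped at 100 iterations (flagged).
  Step acceptance tolerates log-likelihood declines within floating-point
  noise of the log-likelihood magnitude (1e−9 relative); with an absolute
  threshold, fits whose remaining improvement is below representable
  precision stall in the halving loop. Strata without events are dropped
  from the likelihood and logged; separation is flagged as non-convergence.
  Continuous covariates (age, baseline CD4, initiation year) enter through
  4-knot splines; hazard-ratio contrasts at stated values vs a reference
  (e.g. age 50 vs 40) use the basis difference with delta-method intervals.
  The fitter is cross-checked against lifelines (coefficients and
  covariance) and a brute-force partial-likelihood grid search.

## Pipeline and reproducibility

`run_pipeline` executes simulate → inject → sample/audit → post-audit →
derive (×3 versions) → survival (×3) → summaries, writing each stage's
artifacts before the next begins. The master seed spawns per-stage
sub-seeds through `numpy.random.SeedSequence`, so stages are independently
reproducible and the whole run is deterministic. The sensitivity block
restricts both versions to patients present in both (the overlap cohort)
and recomputes the paired incidence estimates. No significance tests are
performed on paired differences; estimates carry 95% intervals.

Problem sizes: the test suite and the acceptance script run the pipeline at
5% of the study-scale preset (~1,250 truth patients; the audit sample stays
at its natural 315-selected / ~250-completed size because it is fixed per
site, not proportional). The CI-coverage experiment uses 2,000-patient
cohorts (50 replicates in the test suite, 30 in the acceptance script).
These sizes keep Monte-Carlo noise well inside the stated tolerances.

## Known limitations

* Inclusion rates among audited records run lower than a real mature cohort
  (~79% vs ~91%) because preset ART-variable missingness translates
  directly into never-initiator misclassification; the mechanism, not the
  level, is the object of study.
* Derived-variable comparisons use exact equality; a one-day time shift is
  as discrepant as a one-year shift.
* No auditor error: the audited version reflects truth wherever a source
  document exists and is read.
* No multiple imputation; Cox fits are complete-case with dropped rows
  counted and reported.
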