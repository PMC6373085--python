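# Methods

This note records the measurement conventions, the synthetic-data model and
the design decisions behind `emrdq`, in enough detail that a reader can
predict exactly what each number means before running anything.

## The assessment model

Data quality is assessed in four domains. *Comparability*: does the practice
population and its disease burden resemble an external standard (a census
population, published prevalence figures)? *Completeness*: what fraction of
real-world observations made it into the record? *Correctness*: what
fraction of recorded observations reflect the true patient state?
*Currency/timeliness*: are the recorded elements recent enough to represent
the patient at a reference time? Eleven measure families operationalize
these domains (see the README table). All measures are counts of patients,
never counts of rows; duplicate rows are deduplicated at load with a logged
count.

### Cohort and ages

Every measure runs on the **complete-case cohort**: patients with
non-missing sex and a computable, non-negative index age. Exclusions are
counted by reason (missing sex, missing birth date, born after the index
date) and `cohort size + exclusions = patient count` is an invariant. The
index date defaults to the extract window start, because a roster described
"as of" a start date measures age there; ages are completed years
(birthday-accurate, not divided by 365.25). Extracts supplying only integer
ages get a birth date imputed at age-years-plus-half-a-year before the
window start (flagged `birth_date_imputed`), which reproduces the stated
completed age at the index date for any index date.

### Case definitions

A definition is a disjunction of clauses; the engine ships editable YAML
defaults:

- diabetes: problem term ∨ antihyperglycemic medication ∨ HbA1c ≥ 6.5% ∨
  fasting glucose ≥ 7.0 mmol/L
- hypertension: problem term ∨ (≥ 2 distinct oral anti-hypertensives ∨ ≥ 1
  diuretic) ∨ ≥ 2 BP readings ≥ 140/90 on distinct dates
- hypothyroidism: problem term ∨ thyroid replacement
- asthma: (problem term ∨ asthma medication) ∧ index age < 18
- obesity: problem term ∨ BMI ≥ 30 from a same-day height+weight pair
- urinary tract infection: problem term ∨ (positive urine culture ∧
  antibiotic within 14 days)

Open design points and how they were settled:

- **Lab/BP thresholds.** Whether the original definitions used thresholds or
  only terms+medications is not observable from the structured defaults we
  had to work from; the thresholds above are standard clinical cutoffs and
  are flagged as assumptions in the YAML. Everything is user-editable.
- **"Two or more oral anti-hypertensives"** is read as two *distinct drugs*
  (by normalized name), not two prescription events.
- **Onset date** is the earliest record contributing to any satisfied
  clause. For count-based clauses (two BP readings, two drugs) that is the
  *first* contributing record, a deliberate, documented simplification.
- **Obesity problem term.** The default obesity definition accepts a
  problem-list entry ("obesity"/"obese") in addition to the BMI rule —
  problem lists are a primary source for every other condition, and clinically
  obesity is routinely carried on the problem list. Users wanting a purely
  anthropometric definition delete that clause.
- **BMI pairing** is strict same-day by default; a relaxed mode pairs the
  nearest height within a configurable gap (height varies slowly in adults),
  off by default because strictness is conservative and testable.
- **Age restriction** (asthma < 18) applies at the index date. Patients
  whose age cannot be computed fail age-restricted definitions.
- Term matching is exact after normalization (lowercase, punctuation
  stripped, whitespace collapsed) plus a shipped synonym dictionary
  ("DM2" ≡ "type ii diabetes mellitus" ≡ `diabetes`). There is deliberately
  no fuzzy matching or NLP: the free-text dialects this tool must handle are
  noisy in case and punctuation, not in vocabulary.

### Measure conventions

- **Windows.** "Within 12 months of onset" = the closed interval
  [onset, onset + 365 d] *after* onset (monitoring follows diagnosis);
  "within 1 year of last visit" = [last visit − 365 d, last visit];
  "within two months" of a pregnancy result = (result, result + 62 d] — a
  fixed-day window because calendar-month arithmetic is ambiguous, and
  exclusive of the result day itself. All window lengths are configurable.
- **Denominators.** BP measures use index age ≥ 18; height/weight all ages.
  The medication-capture denominator is patients with a visit in the final
  365 days of the window. Vitals-timeliness keeps the recording
  denominators minus patients with no visit to anchor on (counted and
  reported); the timeliness numerator is therefore nested in the recording
  numerator by construction. The vaccination denominator is cohort members
  aged ≥ 10 at the window end, and the age rule uses age at administration.
- **A BP "recording"** requires systolic and diastolic on one date; a
  lenient single-component mode exists but is off by default.
- **Undefined ≠ zero.** Every zero-denominator measure carries an explicit
  `undefined` flag; it never renders as 0% or 100%.
- **Chi-squares.** The population-structure test is a goodness-of-fit
  Σ(O−E)²/E over band × sex cells with expected counts from the standard's
  proportions; cells with expected < 5 are pooled into the adjacent band
  within the same sex (logged), df = cells − 1. Stratified
  recording/timeliness tests are contingency chi-squares without continuity
  correction; the default age groups are 0–17 / 18–44 / 45–59 / 60+
  (configurable — the right grouping depends on the population).
- **Standardization** uses 5-year band × sex strata by default (band-only
  mode available). Strata with no cohort members are dropped and the
  standard weights renormalized, with the dropped strata logged. The 95% CI
  is the gamma (Fay–Feuer) interval, the standard choice for directly
  standardized rates. Age-restricted conditions (asthma) report crude
  prevalence only, over the age-restricted subcohort: standardizing a
  truncated age range against a full-population standard is not meaningful.
- **Suppression** is render-only: counts in (0, 5) display as `*` in CSV and
  markdown, while the JSON report retains exact values behind the
  `suppressed` flag so downstream computation is unaffected. Zero renders
  as 0.0 — a true zero is informative, not disclosive.
- **Rounding** is decimal half-up to one decimal for percentages; p-values
  below 0.001 render as `<0.001`.

## The synthetic generator

The generator emulates the *statistical structure* the measures consume — a
roster with an age–sex distribution drawn from a standard-population table,
dated records across all nine tables, configurable prevalence, billing
concordance, recording completeness and timeliness, plus structured vs
free-text problem-list dialects. It deliberately does **not** model disease
progression, visit-pattern realism, seasonality, or correlated
comorbidity; passing tests demonstrate that the measurement machinery is
correct and well-calibrated, not that any particular real extract is of
good quality.

Two properties make every configured rate exactly recoverable:

1. **Signals.** Each true case emits one record its definition detects
   (diabetes: an HbA1c value; hypertension: two high BP pairs on distinct
   dates; obesity: a same-day height/weight pair with BMI in 31–40;
   hypothyroidism/asthma/UTI: a problem-list term). With signal recording at
   its default of 1.0, identified cases equal the ground-truth ledger
   exactly; lowering it is a degradation knob.
2. **Marginal adjustment.** Signal records land in the same tables the
   completeness measures count, so the generic-record probability for
   non-case patients is solved in closed form such that the population
   marginal equals the configured rate: x = (p − π)/(1 − π), where π is the
   realized forced fraction in the measure's own denominator. An infeasible
   configuration (target below the forced fraction) raises a config error
   rather than silently missing its target.

Timeliness uses per-patient latent flags: all of a patient's records of one
vital kind are placed either inside [last visit − 365 d, last visit] or in a
disjoint stale region. Because the obesity height/weight pair moves with
the *weight* flag, the generic-height timely rate is compensated in closed
form so the height marginal still hits its target. Date regions are laid
out to be collision-free: onsets in the first six months of the window,
diabetes follow-up BP within a year of onset (and only for patients already
carrying BP, leaving recording and timeliness marginals untouched), stale
vitals after day 550, and every last visit after day 950 — which is why the
window must span at least ~3.6 years. Consequently:

- the vitals-timeliness *measures* (denominator: all patients) have expected
  value `timeliness × recording`, exposed as
  `GroundTruth.expected_vitals_timeliness`;
- the diabetes BP-follow-up measure has expected value
  `f × P(has BP | diabetic case)`, exposed as
  `expected_bp_followup_diabetes`;
- billing follows the two-coin-flip model (cases billed with probability =
  sensitivity, non-cases with the false-billing rate), so expected PPV is
  `n_case·s / (n_case·s + n_non·f)` at the realized case count
  (`expected_ppv`);
- the BP-follow-up measure for patients on hypertension medication is
  structurally ≈ 100% here, because medicated hypertensives are cases whose
  onset is their first high BP reading — a known, documented degeneracy of
  the synthetic model, not of the measure.

Prevalence semantics: hypertension is drawn among adults (18+), asthma among
under-18s, the rest across the whole cohort; the recovery target for each is
its eligible subpopulation. Non-followed pregnancy positives have their
random extra visits kept out of the follow-up window by construction, so the
follow-up rate is recovered exactly. The default rates (e.g. prevalence
12% diabetes / 28% hypertension / 7% hypothyroidism; recording 85% BP / 60%
height / 70% weight; timely fractions 80/45/60%) were chosen once as values
a primary-care data-quality study would consider realistic and are fixed as
the package's study conditions.

Determinism: one `numpy` Generator seeded from `SynthConfig.seed` drives
everything; identical configs produce byte-identical extracts, reports and
ledgers.

### Degradation

`degrade` supports row deletion (per-table fractions or whole tables) and
back-dating of vitals. Deletion is monotone for every completeness and
currency measure *when the gold standard is held fixed*; the test suite
asserts exactly that, pairing each knob with the measures it degrades
(e.g. billing deletion with sensitivity at fixed cases), because a knob that
also shrinks the gold set can otherwise move a ratio either way — deleting
the records that define cases removes patients from numerator and
denominator together. Back-dating is monotone for last-visit-anchored
timeliness (no vitals exist after the last visit, so records can only leave
the window); it is asserted for those measures.

## Problem sizes used in testing

Oracle-equivalence tests run on 200-patient fixtures against brute-force
loop implementations at 1e-12 relative tolerance. Parameter recovery runs
20 seeds at n = 10,000 and requires each configured rate inside 3 binomial
standard errors in ≥ 19 of 20 seeds — these sizes give the recovery test
sub-percentage-point resolution while keeping the whole suite comfortably
under a minute per seed. The acceptance script uses a single n = 10,000 run.

## Known limitations

- Term matching is dictionary-based; truly novel spellings of a condition
  are missed (by design — no NLP).
- The gamma CI assumes independent binomial strata; extracts with clustered
  patients (by physician or site) will have anti-conservative intervals.
- The synthetic generator's degeneracies listed above (hypertension-med
  follow-up ≈ 100%) mean those measures exercise plumbing, not calibration.
- Specificity/NPV are out of scope: without a true-negative gold standard,
  only sensitivity and PPV are estimable from the record itself.
- Population-pyramid plotting and indirect standardization are out of scope.
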