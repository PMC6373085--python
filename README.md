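# emrdq — data-quality measures for primary health care EMR extracts

Researchers who reuse electronic medical record (EMR) data — for disease
surveillance, quality-of-care reporting, or epidemiological studies — need to
know whether the data are fit for that purpose before trusting any estimate
derived from them. `emrdq` implements a basic assessment model for primary
health care EMR extracts: **eleven operational measures in four domains**,
computed over a relational extract (patients, visits, problem list,
medications, labs, vitals, billing, immunizations, allergies) and driven by
editable case definitions for six test conditions (diabetes, hypertension,
hypothyroidism, asthma, obesity, urinary tract infection).

| Domain | Measures |
|---|---|
| **Comparability** | age–sex structure vs a standard population (goodness-of-fit χ² over 5-year band × sex cells, mean/median age); crude and directly age–sex standardized prevalence of the test conditions vs user-supplied published figures |
| **Completeness** | sensitivity of billing codes against the case definitions; "consistency of capture" (≥1 problem-list entry; ≥1 allergy entry incl. the "no known allergies" marker; ≥1 medication among patients visiting in the final year); BP/height/weight recording with sex and age-group χ²; BP recording within 12 months of diabetes onset and among patients on hypertension medications |
| **Correctness** | positive predictive value of billing codes; unlikely age × procedure combinations (tetanus toxoid conjugate vaccine administered at age ≥ 10) |
| **Currency** | weight recording within 1 year of the last visit for obese patients; a visit within 62 days of a positive pregnancy test; BP/height/weight recorded within 1 year of the last visit |

The core quantities are the familiar screening and standardization formulas.
With a case-definition gold standard *G* and billing-positive set *B* on one
cohort,

    sensitivity = |G ∩ B| / |G|        PPV = |G ∩ B| / |B|

and the directly standardized prevalence over strata *s* (5-year age band ×
sex) with standard-population weights *w_s* and stratum rates *r_s = x_s/n_s*
is

    p_std = Σ_s w_s r_s,   with a gamma (Fay–Feuer) 95% interval.

A patient is a *case* if any clause of the condition's definition fires —
problem-list terms (normalized and synonym-mapped), medication lists with
distinct-drug minimums, lab thresholds (e.g. HbA1c ≥ 6.5%), two high BP
readings on distinct dates, or BMI ≥ 30 from a same-day height/weight pair —
and the onset date is the earliest contributing record. All terms and
thresholds live in YAML, not code, because a case definition is a
fitness-for-purpose decision.

Because real practice extracts cannot be redistributed, the package includes
a **synthetic extract generator** with fully configured population structure,
prevalence, billing concordance (a two-coin-flip model with analytically
known sensitivity and PPV), recording completeness and timeliness — plus a
ground-truth ledger, so the entire pipeline is testable end to end and every
configured rate is recoverable by the measure that targets it.

## Worked example

```python
from emrdq import SynthConfig, generate, run_assessment

extract, truth = generate(SynthConfig(n_patients=10_000, seed=4))
report = run_assessment(extract)
for r in report.results:
    if r.measure_id in ("prevalence_diabetes", "sensitivity_diabetes",
                        "ppv_diabetes", "bp_recording", "weight_timeliness_obesity",
                        "pregnancy_followup"):
        print(f"{r.domain:13s} {r.measure_id:28s} "
              f"{'' if r.value_pct is None else round(r.value_pct, 1):>6} "
              f"({r.numerator}/{r.denominator})")
```

prints

```
comparability prevalence_diabetes            12.3 (1226/9957)
completeness  sensitivity_diabetes           85.4 (1047/1226)
correctness   ppv_diabetes                   92.2 (1047/1135)
completeness  bp_recording                   85.0 (6592/7752)
currency      weight_timeliness_obesity      60.4 (1525/2523)
currency      pregnancy_followup             63.2 (60/95)
```

Reading it: of 9,957 complete-case patients, 12.3% meet the diabetes
definition (the generator was configured at 12%); billing codes catch 85.4%
of those cases (configured 85%) and 92.2% of billed patients truly qualify —
the two-coin-flip billing model predicts 92.3% here. BP is recorded for 85.0%
of adults, 60.4% of obese patients have a weight within a year of their last
visit, and 63.2% of positive pregnancy tests are followed by a visit within
62 days. Counts below the suppression threshold (5) render as `*`; empty
denominators render as `undefined`, never as 0% or 100%.

The same pipeline runs from the shell:

```bash
emrdq synth  --out extract/ --seed 4                 # nine CSVs + ground_truth.csv
emrdq cases  --extract extract/ --out cases.csv
emrdq assess --extract extract/ --out report/ --format json,csv,markdown
```

Real extracts are loaded from the same nine-CSV layout with
`emrdq.load_extract(directory, window=(start, end))`; loading validates
referential integrity and dates row by row and refuses to drop bad rows
silently. Extracts missing whole tables (some EMR products cannot export
labs or a structured problem list) still produce a full report in which the
affected measures carry machine-readable not-computable reasons and
definitions degrade clause by clause.

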