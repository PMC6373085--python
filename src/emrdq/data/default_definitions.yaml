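# Default case definitions for the six test conditions.
#
# Every threshold and term list here is editable configuration, not code:
# "fitness for purpose" means each project should review and adapt these
# rules before use. A patient is a case if ANY clause is satisfied; the
# onset date is the earliest record contributing to a satisfied clause.
# Lab thresholds are flagged assumptions chosen from standard clinical
# practice (HbA1c >= 6.5%, fasting glucose >= 7.0 mmol/L, BP >= 140/90,
# BMI >= 30).
definitions:
  diabetes:
    clauses:
      - problem_terms: [diabetes]
      - medications:
          names: [metformin, glyburide, gliclazide, sitagliptin, insulin, insulin glargine]
          min_distinct: 1
      - lab: {test_code: hba1c, comparator: ">=", threshold: 6.5, units: "%"}
      - lab: {test_code: glucose_fasting, comparator: ">=", threshold: 7.0, units: "mmol/L"}
  hypertension:
    clauses:
      - problem_terms: [hypertension]
      - medications:
          names: [amlodipine, ramipril, lisinopril, losartan, candesartan, metoprolol,
                  atenolol, nifedipine, perindopril, valsartan]
          min_distinct: 2
      - medications:
          names: [hydrochlorothiazide, furosemide, indapamide, chlorthalidone, spironolactone]
          min_distinct: 1
      - bp: {systolic: 140, diastolic: 90, min_count: 2, distinct_dates: true}
  hypothyroidism:
    clauses:
      - problem_terms: [hypothyroidism]
      - medications:
          names: [levothyroxine, synthroid, liothyronine, desiccated thyroid]
          min_distinct: 1
  asthma:
    age_max: 17
    clauses:
      - problem_terms: [asthma]
      - medications:
          names: [salbutamol, ventolin, fluticasone, flovent, budesonide, montelukast,
                  formoterol, terbutaline]
          min_distinct: 1
  obesity:
    clauses:
      - problem_terms: [obesity]
      - bmi: {threshold: 30.0, max_pair_gap_days: 0}
  urinary_tract_infection:
    clauses:
      - problem_terms: [urinary tract infection]
      - lab_med_combo:
          lab: {test_code: urine_culture, qualitative: positive}
          medications:
            names: [nitrofurantoin, ciprofloxacin, trimethoprim, sulfamethoxazole trimethoprim,
                    cephalexin, amoxicillin, fosfomycin]
          window_days: 14

# Billing diagnostic codes (3-digit ICD-9 style) used as the comparison
# standard for sensitivity and positive predictive value.
billing_codes:
  diabetes: ["250"]
  hypertension: ["401", "402"]
  hypothyroidism: ["244"]
  asthma: ["493"]
  obesity: ["278"]
  urinary_tract_infection: ["595", "599"]
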