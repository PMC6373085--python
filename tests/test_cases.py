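"""Term normalization and the case-definition rule engine."""

from __future__ import annotations

import pandas as pd
import pytest

from emrdq.cases import (
    CaseDefinition,
    DefinitionError,
    LabClause,
    ProblemTermClause,
    billing_positives,
    evaluate,
    identify_cases,
    load_definitions,
    normalize_term,
)
from emrdq.model import complete_case_cohort

from conftest import make_extract, patient


class TestNormalizeTerm:
    @pytest.mark.parametrize(
        "text,token",
        [
            ("Type II Diabetes Mellitus", "diabetes"),
            ("DM2", "diabetes"),
            ("diabetes mellitus type 2", "diabetes"),
            ("  HTN ", "hypertension"),
            ("UTI", "urinary tract infection"),
            ("", ""),
        ],
    )
    def test_synonym_closure(self, text, token):
        assert normalize_term(text) == token

    def test_unknown_terms_fall_back_to_basic_normalization(self):
        assert normalize_term("Left KNEE pain!!") == "left knee pain"


class TestEvaluate:
    def test_lab_threshold_makes_case_with_lab_onset(self, definitions):
        ex = make_extract(
            patients=[patient("a")],
            labs=[{"patient_id": "a", "event_date": "2008-08-09",
                   "test_code": "hba1c", "value": 7.2, "units": "%"}],
        )
        is_case, onset = evaluate(ex, definitions["diabetes"], "a")
        assert is_case and onset == pd.Timestamp("2008-08-09")

    def test_below_threshold_is_not_case(self, definitions):
        ex = make_extract(
            patients=[patient("a")],
            labs=[{"patient_id": "a", "event_date": "2008-08-09",
                   "test_code": "hba1c", "value": 6.1, "units": "%"}],
        )
        assert evaluate(ex, definitions["diabetes"], "a") == (False, None)

    def test_patient_with_no_records_is_never_a_case(self, definitions):
        ex = make_extract(patients=[patient("a")])
        for definition in definitions.values():
            assert evaluate(ex, definition, "a") == (False, None)

    def test_bmi_from_same_day_pair(self, definitions):
        # 80 kg at 1.60 m -> BMI 31.25 >= 30
        ex = make_extract(
            patients=[patient("a")],
            vitals=[{"patient_id": "a", "event_date": "2009-09-10",
                     "kind": "weight", "value": 80.0, "units": "kg"},
                    {"patient_id": "a", "event_date": "2009-09-10",
                     "kind": "height", "value": 1.60, "units": "m"}],
        )
        is_case, onset = evaluate(ex, definitions["obesity"], "a")
        assert is_case and onset == pd.Timestamp("2009-09-10")

    def test_bmi_needs_same_day_by_default(self, definitions):
        ex = make_extract(
            patients=[patient("a")],
            vitals=[{"patient_id": "a", "event_date": "2009-09-10",
                     "kind": "weight", "value": 80.0, "units": "kg"},
                    {"patient_id": "a", "event_date": "2009-09-12",
                     "kind": "height", "value": 1.60, "units": "m"}],
        )
        assert evaluate(ex, definitions["obesity"], "a")[0] is False

    def test_hypertension_needs_two_high_bp_dates(self, definitions):
        vit = [
            {"patient_id": "a", "event_date": "2008-01-01", "kind": "systolic_bp",
             "value": 150, "units": "mmHg"},
            {"patient_id": "a", "event_date": "2008-01-01", "kind": "diastolic_bp",
             "value": 95, "units": "mmHg"},
        ]
        one = make_extract(patients=[patient("a")], vitals=vit)
        assert evaluate(one, definitions["hypertension"], "a")[0] is False
        two = make_extract(
            patients=[patient("a")],
            vitals=vit + [
                {"patient_id": "a", "event_date": "2008-03-01", "kind": "systolic_bp",
                 "value": 145, "units": "mmHg"},
                {"patient_id": "a", "event_date": "2008-03-01", "kind": "diastolic_bp",
                 "value": 88, "units": "mmHg"},
            ],
        )
        is_case, onset = evaluate(two, definitions["hypertension"], "a")
        assert is_case and onset == pd.Timestamp("2008-01-01")

    def test_two_distinct_antihypertensives_qualify(self, definitions):
        meds = [{"patient_id": "a", "event_date": "2008-01-01", "name": "Ramipril 5mg"},
                {"patient_id": "a", "event_date": "2008-02-01", "name": "amlodipine"}]
        ex = make_extract(patients=[patient("a")], medications=meds)
        assert evaluate(ex, definitions["hypertension"], "a")[0] is True
        # the same drug twice is one distinct agent
        ex1 = make_extract(
            patients=[patient("a")],
            medications=[{"patient_id": "a", "event_date": "2008-01-01",
                          "name": "ramipril"},
                         {"patient_id": "a", "event_date": "2008-02-01",
                          "name": "ramipril"}],
        )
        assert evaluate(ex1, definitions["hypertension"], "a")[0] is False

    def test_uti_combo_requires_antibiotic_within_window(self, definitions):
        base = dict(
            patients=[patient("a")],
            labs=[{"patient_id": "a", "event_date": "2008-01-01",
                   "test_code": "urine_culture", "qualitative": "positive",
                   "value": None, "units": None}],
        )
        near = make_extract(
            medications=[{"patient_id": "a", "event_date": "2008-01-10",
                          "name": "nitrofurantoin"}], **base)
        far = make_extract(
            medications=[{"patient_id": "a", "event_date": "2008-02-01",
                          "name": "nitrofurantoin"}], **base)
        assert evaluate(near, definitions["urinary_tract_infection"], "a")[0] is True
        assert evaluate(far, definitions["urinary_tract_infection"], "a")[0] is False

    def test_asthma_age_restriction_blocks_adults(self, definitions):
        ex = make_extract(
            patients=[patient("a", birth="1966-01-01")],  # age 40 at index
            problems=[{"patient_id": "a", "event_date": "2008-01-01",
                       "text": "asthma"}],
        )
        assert evaluate(ex, definitions["asthma"], "a")[0] is False
        child = make_extract(
            patients=[patient("k", birth="2000-01-01")],
            problems=[{"patient_id": "k", "event_date": "2008-01-01",
                       "text": "asthma"}],
        )
        assert evaluate(child, definitions["asthma"], "k")[0] is True

    def test_unit_mismatch_is_definition_error(self, definitions):
        ex = make_extract(
            patients=[patient("a")],
            labs=[{"patient_id": "a", "event_date": "2008-08-09",
                   "test_code": "hba1c", "value": 55.0, "units": "mmol/mol"}],
        )
        with pytest.raises(DefinitionError):
            evaluate(ex, definitions["diabetes"], "a")


class TestIdentifyCases:
    def test_empty_clause_list_rejected(self):
        with pytest.raises(DefinitionError):
            CaseDefinition("diabetes", clauses=[])

    def test_matches_brute_force_per_patient_evaluation(self, definitions, synth_small):
        """identify_cases must equal the map of per-patient evaluation."""
        ex, _ = synth_small
        cohort = complete_case_cohort(ex)
        sample = cohort.members["patient_id"].iloc[:100]
        for cond in ("diabetes", "hypertension", "obesity", "asthma"):
            cs = identify_cases(ex, definitions[cond], cohort)
            table = cs.table.set_index("patient_id")
            for pid in sample:
                is_case, onset = evaluate(ex, definitions[cond], pid)
                assert bool(table.loc[pid, "is_case"]) == is_case
                if is_case:
                    assert table.loc[pid, "onset_date"] == onset

    def test_ledger_oracle_with_full_recording(self, definitions, synth_small):
        """With signal recording at 1.0, identified cases equal the ground
        truth exactly, per condition."""
        ex, truth = synth_small
        cohort = complete_case_cohort(ex)
        coh_ids = set(cohort.patient_ids)
        for cond, definition in definitions.items():
            cs = identify_cases(ex, definition, cohort)
            assert cs.case_ids == (truth.cases(cond) & coh_ids)

    def test_monotone_in_added_records(self, definitions):
        """Adding records never revokes case status nor delays onset."""
        ex = make_extract(
            patients=[patient("a")],
            labs=[{"patient_id": "a", "event_date": "2008-08-09",
                   "test_code": "hba1c", "value": 7.2, "units": "%"}],
        )
        was_case, old_onset = evaluate(ex, definitions["diabetes"], "a")
        richer = make_extract(
            patients=[patient("a")],
            labs=[{"patient_id": "a", "event_date": "2008-08-09",
                   "test_code": "hba1c", "value": 7.2, "units": "%"}],
            problems=[{"patient_id": "a", "event_date": "2007-02-02",
                       "text": "diabetes mellitus"}],
            medications=[{"patient_id": "a", "event_date": "2009-01-01",
                          "name": "metformin"}],
        )
        is_case, onset = evaluate(richer, definitions["diabetes"], "a")
        assert was_case and is_case
        assert onset <= old_onset


class TestBillingPositives:
    def test_empty_billing_table(self, billing_codes):
        ex = make_extract(patients=[patient("a")])
        cohort = complete_case_cohort(ex)
        assert billing_positives(ex, "diabetes", billing_codes, cohort) == set()

    def test_codes_match_after_trimming(self, billing_codes):
        ex = make_extract(
            patients=[patient("a"), patient("b")],
            billing=[{"patient_id": "a", "event_date": "2008-01-01", "code": "250 "},
                     {"patient_id": "b", "event_date": "2008-01-01", "code": "251"}],
        )
        cohort = complete_case_cohort(ex)
        assert billing_positives(ex, "diabetes", billing_codes, cohort) == {"a"}

    def test_non_cohort_members_excluded(self, billing_codes):
        ex = make_extract(
            patients=[patient("a"), {"patient_id": "b", "sex": None,
                                     "birth_date": "1970-01-01"}],
            billing=[{"patient_id": "a", "event_date": "2008-01-01", "code": "250"},
                     {"patient_id": "b", "event_date": "2008-01-01", "code": "250"}],
        )
        cohort = complete_case_cohort(ex)
        assert billing_positives(ex, "diabetes", billing_codes, cohort) == {"a"}
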