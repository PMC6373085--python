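"""Extract loading, validation, cohort construction and age banding."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emrdq.model import (
    ExtractValidationError,
    age_band,
    age_band_labels,
    age_at,
    assign_age_bands,
    complete_case_cohort,
    extracts_equal,
    last_visit_date,
    load_extract,
    write_extract,
)
from emrdq.synth import SynthConfig, generate

from conftest import make_extract, patient


class TestLoadExtract:
    def test_empty_record_tables_are_valid(self):
        ex = make_extract(patients=[patient("a")])
        assert ex.n_patients == 1
        assert ex.visits.empty

    def test_zero_patients_is_valid(self, tmp_path):
        ex = make_extract()
        write_extract(ex, tmp_path)
        loaded = load_extract(tmp_path)
        assert loaded.n_patients == 0

    def test_orphan_row_fails_with_row_number(self, tmp_path):
        # a medication row referencing an unknown patient must be rejected
        write_extract(make_extract(patients=[patient("a"), patient("b"), patient("c")]),
                      tmp_path)
        (tmp_path / "medications.csv").write_text(
            "patient_id,event_date,name,class_code\nzz,2007-01-01,metformin,\n"
        )
        with pytest.raises(ExtractValidationError) as err:
            load_extract(tmp_path)
        assert any("zz" in e and "row 1" in e for e in err.value.errors)

    def test_missing_required_column_is_schema_error(self, tmp_path):
        write_extract(make_extract(patients=[patient("a")]), tmp_path)
        (tmp_path / "visits.csv").write_text("patient_id\na\n")
        with pytest.raises(ExtractValidationError) as err:
            load_extract(tmp_path)
        assert any("missing required column" in e for e in err.value.errors)

    def test_unparseable_date_is_row_error(self, tmp_path):
        write_extract(make_extract(patients=[patient("a")]), tmp_path)
        (tmp_path / "visits.csv").write_text(
            "patient_id,event_date\na,2007-01-01\na,not-a-date\n"
        )
        with pytest.raises(ExtractValidationError) as err:
            load_extract(tmp_path)
        assert any("unparseable date" in e for e in err.value.errors)

    def test_round_trip_identity(self, tmp_path):
        ex = make_extract(
            patients=[patient("a"), patient("b", sex="male", birth="1990-03-04"),
                      patient("c"), patient("d"), patient("e")],
            visits=[{"patient_id": "a", "event_date": "2008-01-02"},
                    {"patient_id": "b", "event_date": "2010-03-04"}],
            problems=[{"patient_id": "a", "event_date": "2007-05-06",
                       "text": "asthma", "code": None}],
            medications=[{"patient_id": "b", "event_date": "2007-06-07",
                          "name": "metformin"}],
            labs=[{"patient_id": "c", "event_date": "2008-08-09",
                   "test_code": "hba1c", "value": 7.2, "units": "%"}],
            vitals=[{"patient_id": "d", "event_date": "2009-09-10",
                     "kind": "weight", "value": 80.0, "units": "kg"},
                    {"patient_id": "d", "event_date": "2009-09-10",
                     "kind": "height", "value": 1.6, "units": "m"}],
            billing=[{"patient_id": "a", "event_date": "2007-05-06", "code": "493"}],
            immunizations=[{"patient_id": "e", "event_date": "2006-02-03",
                            "vaccine": "DTaP-IPV-Hib"}],
            allergies=[{"patient_id": "a", "event_date": "2006-01-05",
                        "substance": "no known allergies"},
                       {"patient_id": "b", "event_date": "2006-01-06",
                        "substance": "penicillin"},
                       {"patient_id": "c", "event_date": "2006-01-07",
                        "substance": "sulfa"}],
        )
        write_extract(ex, tmp_path)
        assert extracts_equal(ex, load_extract(tmp_path))

    def test_synthetic_round_trip(self, tmp_path, synth_small):
        ex, _ = synth_small
        write_extract(ex, tmp_path)
        assert extracts_equal(ex, load_extract(tmp_path))

    def test_duplicate_rows_deduplicated_with_log(self):
        ex = make_extract(
            patients=[patient("a")],
            visits=[{"patient_id": "a", "event_date": "2008-01-02"},
                    {"patient_id": "a", "event_date": "2008-01-02"}],
        )
        assert len(ex.visits) == 1
        assert any("duplicate" in line for line in ex.log)

    def test_integer_age_dialect_imputes_birth_date(self, tmp_path):
        (tmp_path / "patients.csv").write_text("patient_id,sex,age\na,female,35\n")
        ex = load_extract({"patients": tmp_path / "patients.csv"},
                          window=("2006-01-01", "2010-12-31"))
        assert ex.patients["birth_date"].notna().all()
        assert bool(ex.patients["birth_date_imputed"].iloc[0])
        cohort = complete_case_cohort(ex)
        assert cohort.members["index_age"].iloc[0] == 35


class TestCohort:
    def test_exclusion_accounting(self):
        ex = make_extract(
            patients=[patient("a"), patient("b"),
                      {"patient_id": "c", "sex": None, "birth_date": "1980-01-01"},
                      {"patient_id": "d", "sex": "male", "birth_date": None}],
        )
        cohort = complete_case_cohort(ex)
        assert len(cohort) == 2
        assert cohort.exclusions["missing_sex"] == 1
        assert cohort.exclusions["missing_age"] == 1
        assert len(cohort) + sum(cohort.exclusions.values()) == ex.n_patients

    def test_index_age_is_completed_years_at_window_start(self):
        ex = make_extract(patients=[patient("a", birth="1970-06-01")])
        cohort = complete_case_cohort(ex, index_date="2006-01-01")
        assert cohort.members["index_age"].iloc[0] == 35
        assert age_at("1970-06-01", "2006-01-01") == 35
        assert age_at("1970-06-01", "2006-06-01") == 36

    def test_all_complete_is_noop_filter(self):
        ex = make_extract(patients=[patient(f"p{i}") for i in range(7)])
        assert len(complete_case_cohort(ex)) == 7

    def test_born_after_index_is_excluded(self):
        ex = make_extract(patients=[patient("a", birth="2007-06-01")])
        cohort = complete_case_cohort(ex, index_date="2006-01-01")
        assert len(cohort) == 0
        assert cohort.exclusions["negative_age"] == 1


class TestLastVisit:
    def test_max_none_and_tie(self):
        ex = make_extract(
            patients=[patient("a"), patient("b"), patient("c")],
            visits=[{"patient_id": "a", "event_date": "2008-01-02"},
                    {"patient_id": "a", "event_date": "2010-03-04"},
                    {"patient_id": "c", "event_date": "2009-05-05"},
                    {"patient_id": "c", "event_date": "2009-05-05"}],
        )
        assert last_visit_date(ex, "a") == pd.Timestamp("2010-03-04").date()
        assert last_visit_date(ex, "b") is None
        assert last_visit_date(ex, "c") == pd.Timestamp("2009-05-05").date()
        with pytest.raises(KeyError):
            last_visit_date(ex, "nope")


class TestAgeBand:
    @pytest.mark.parametrize(
        "age,label",
        [(0, "0-4"), (4, "0-4"), (5, "5-9"), (41, "40-44"), (84, "80-84"),
         (85, "85+"), (104, "85+")],
    )
    def test_examples(self, age, label):
        assert age_band(age) == label

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            age_band(-1)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=130))
    def test_partition_disjoint_and_exhaustive(self, age):
        label = age_band(age)
        labels = age_band_labels()
        assert label in labels
        if label.endswith("+"):
            assert age >= int(label[:-1])
        else:
            lo, hi = map(int, label.split("-"))
            assert lo <= age <= hi

    def test_vectorized_matches_scalar(self):
        ages = list(range(0, 120))
        assert list(assign_age_bands(ages)) == [age_band(a) for a in ages]
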