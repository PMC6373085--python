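"""Correctness and currency measures.

Correctness: positive predictive value of billing codes against the case
definitions, and the unlikely age-by-procedure combination (tetanus toxoid
conjugate vaccination at age 10+). Currency: three timeliness measures
anchored on onset, last visit or a positive pregnancy test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .cases import CaseSet, normalize_term
from .completeness import (
    DEFAULT_AGE_GROUPS,
    ConcordanceResult,
    RecordingResult,
    StratumTest,
    _anchored_fraction,
    _bp_dates,
    _proportion,
    patients_with_vital,
    stratified_tests,
)
from .model import Cohort, EmrExtract, _completed_years, last_visit_series

__all__ = [
    "TimelinessResult",
    "DEFAULT_VACCINE_TERMS",
    "ppv",
    "unlikely_vaccination",
    "weight_timeliness_obesity",
    "pregnancy_followup",
    "vitals_timeliness",
]

#: normalized immunization names counted as a tetanus toxoid conjugate
#: vaccine (DTaP-IPV-Hib and variants); extend via configuration.
DEFAULT_VACCINE_TERMS: tuple[str, ...] = ("tetanus_conjugate_vaccine",)


@dataclass
class TimelinessResult:
    measure: str
    numerator: int
    denominator: int
    pct: float | None
    window_days: int
    undefined: bool = False
    excluded_no_visit: int = 0
    sex_test: StratumTest | None = None
    age_test: StratumTest | None = None


def ppv(gold: CaseSet, billing: set[str]) -> ConcordanceResult:
    """Positive predictive value of billing codes:
    100 * |gold ∩ billing| / |billing|, undefined when billing is empty."""
    gold_ids = gold.case_ids
    overlap = gold_ids & set(billing)
    pct, undef = _proportion(len(overlap), len(billing))
    return ConcordanceResult(
        condition_id=gold.condition_id,
        n_gold=len(gold_ids),
        n_billing=len(billing),
        n_overlap=len(overlap),
        value_pct=pct,
        kind="ppv",
        undefined=undef,
    )


def unlikely_vaccination(
    extract: EmrExtract,
    cohort: Cohort,
    vaccine_terms: Sequence[str] = DEFAULT_VACCINE_TERMS,
    min_age: int = 10,
) -> RecordingResult:
    """Percentage of patients aged ``min_age``+ with a tetanus toxoid
    conjugate vaccine administered at ``min_age`` or older.

    The age rule uses the age at administration, not the current age: the
    vaccine is ordinarily reserved for younger children, so a record of it
    given to an older patient flags a likely mis-recording. The denominator
    is cohort members aged ``min_age``+ at the window end.
    """
    members = cohort.members.merge(
        extract.patients[["patient_id", "birth_date"]], on="patient_id"
    )
    end = pd.Timestamp(extract.window_end)
    age_at_end = _completed_years(members["birth_date"], end)
    eligible = members[age_at_end >= min_age]
    den = len(eligible)

    imm = extract.table("immunizations")
    num_ids: set[str] = set()
    if not imm.empty and den:
        tokens = imm["vaccine"].map(lambda v: normalize_term(v))
        hits = imm[tokens.isin(set(vaccine_terms))].merge(
            eligible[["patient_id", "birth_date"]], on="patient_id"
        )
        if not hits.empty:
            age_at_event = _completed_years(hits["birth_date"], hits["event_date"])
            num_ids = set(hits.loc[age_at_event >= min_age, "patient_id"])
    pct, undef = _proportion(len(num_ids), den)
    return RecordingResult("unlikely_vaccination", len(num_ids), den, pct, undef)


def weight_timeliness_obesity(
    extract: EmrExtract, obesity_cases: CaseSet, window_days: int = 365
) -> TimelinessResult:
    """Obese patients with >=1 weight recording within a year before (or on)
    their last visit. Cases without any visit have no anchor and are
    excluded from the denominator (counted in ``excluded_no_visit``)."""
    lv = last_visit_series(extract)
    case_ids = obesity_cases.case_ids
    anchors = lv[lv.index.isin(case_ids)]
    excluded = len(case_ids) - len(anchors)
    w = extract.vitals
    weights = w.loc[w["kind"] == "weight", ["patient_id", "event_date"]]
    num, den = _anchored_fraction(weights, anchors, window_days, "before")
    pct, undef = _proportion(num, den)
    return TimelinessResult(
        "weight_timeliness_obesity", num, den, pct, window_days, undef, excluded
    )


def pregnancy_followup(
    extract: EmrExtract,
    cohort: Cohort,
    test_code: str = "pregnancy_hcg",
    window_days: int = 62,
) -> TimelinessResult:
    """Patients with a positive pregnancy laboratory result and >=1 visit
    within ``window_days`` after (but not on) the result date.

    Two months is fixed at 62 days: calendar-month arithmetic is ambiguous
    across month lengths, a fixed-day window is reproducible. A patient with
    several positive results counts if any result has a qualifying visit.
    """
    labs = extract.labs
    ids = set(cohort.patient_ids)
    qual = labs["qualitative"].astype("string").str.strip().str.lower()
    code = labs["test_code"].astype("string").str.strip()
    pos = labs[(code == test_code) & (qual == "positive")]
    pos = pos[pos["patient_id"].isin(ids)]
    den = int(pos["patient_id"].nunique())
    if den == 0:
        return TimelinessResult("pregnancy_followup", 0, 0, None, window_days, True)
    visits = extract.visits[extract.visits["patient_id"].isin(set(pos["patient_id"]))]
    joined = pos[["patient_id", "event_date"]].merge(
        visits, on="patient_id", suffixes=("_lab", "_visit")
    )
    delta = (joined["event_date_visit"] - joined["event_date_lab"]).dt.days
    ok = (delta >= 1) & (delta <= window_days)
    num = int(joined.loc[ok, "patient_id"].nunique())
    pct, undef = _proportion(num, den)
    return TimelinessResult("pregnancy_followup", num, den, pct, window_days, undef)


def vitals_timeliness(
    extract: EmrExtract,
    cohort: Cohort,
    kind: str,
    window_days: int = 365,
    age_groups: Sequence[tuple[int, int | None]] = DEFAULT_AGE_GROUPS,
    lenient_bp: bool = False,
    adult_age: int = 18,
) -> TimelinessResult:
    """Proportion of patients whose latest-year record exists: >=1 value of
    ``kind`` within ``window_days`` before (or on) the last visit.

    Denominators mirror :func:`~emrdq.completeness.vitals_recording` (BP
    restricted to adults), minus patients with no visit to anchor on
    (logged in ``excluded_no_visit``).
    """
    members = cohort.members
    if kind == "bp":
        members = members[members["index_age"] >= adult_age]
        records = _bp_dates(extract, lenient=lenient_bp)
    elif kind in ("height", "weight"):
        v = extract.vitals
        records = v.loc[v["kind"] == kind, ["patient_id", "event_date"]]
    else:
        raise ValueError(f"unknown vitals kind {kind!r}")
    lv = last_visit_series(extract)
    ids = set(members["patient_id"])
    anchors = lv[lv.index.isin(ids)]
    excluded = len(ids) - len(anchors)
    if anchors.empty or records.empty:
        num_ids: set[str] = set()
    else:
        joined = records.merge(anchors.rename("anchor"), left_on="patient_id", right_index=True)
        delta = (joined["event_date"] - joined["anchor"]).dt.days
        ok = (delta >= -window_days) & (delta <= 0)
        num_ids = set(joined.loc[ok, "patient_id"])
    den = len(anchors)
    pct, undef = _proportion(len(num_ids), den)
    anchored_members = members[members["patient_id"].isin(set(anchors.index))]
    if len(anchored_members):
        sex_test, age_test = stratified_tests(anchored_members, num_ids, age_groups)
    else:
        sex_test = age_test = StratumTest(None, None, None, undefined=True)
    return TimelinessResult(
        measure=f"{kind}_timeliness",
        numerator=len(num_ids),
        denominator=den,
        pct=pct,
        window_days=window_days,
        undefined=undef,
        excluded_no_visit=excluded,
        sex_test=sex_test,
        age_test=age_test,
    )
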