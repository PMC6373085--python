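"""Completeness measures: case capture vs billing, consistency of capture,
vitals recording and blood-pressure recording among patients requiring it.

All proportions are counts of patients, never counts of rows. Zero
denominators propagate as explicit ``undefined`` flags, never as 0% or
100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cases import CaseSet, _vitals_pairs
from .model import NO_KNOWN_ALLERGIES, Cohort, EmrExtract

__all__ = [
    "DEFAULT_AGE_GROUPS",
    "ConcordanceResult",
    "RecordingResult",
    "StratumTest",
    "sensitivity",
    "consistency_of_capture",
    "vitals_recording",
    "bp_among_requiring",
    "patients_with_bp",
    "patients_with_vital",
]

#: default age groups for stratified chi-squares (upper bound inclusive;
#: None = open-ended). Fully configurable — analyses should pick groups
#: matching their population.
DEFAULT_AGE_GROUPS: tuple[tuple[int, int | None], ...] = (
    (0, 17),
    (18, 44),
    (45, 59),
    (60, None),
)


def age_group_label(lo: int, hi: int | None) -> str:
    return f"{lo}+" if hi is None else f"{lo}-{hi}"


@dataclass
class StratumTest:
    statistic: float | None
    df: int | None
    p: float | None
    table: dict[str, tuple[int, int]] = field(default_factory=dict)  # stratum -> (num, den)
    undefined: bool = False


@dataclass
class ConcordanceResult:
    """Agreement between a case definition (gold) and billing codes."""

    condition_id: str
    n_gold: int
    n_billing: int
    n_overlap: int
    value_pct: float | None
    kind: str = "sensitivity"  # or "ppv"
    undefined: bool = False

    @property
    def sensitivity_pct(self) -> float | None:
        return self.value_pct if self.kind == "sensitivity" else None


@dataclass
class RecordingResult:
    measure: str
    numerator: int
    denominator: int
    pct: float | None
    undefined: bool = False
    sex_test: StratumTest | None = None
    age_test: StratumTest | None = None


def _proportion(num: int, den: int) -> tuple[float | None, bool]:
    if den == 0:
        return None, True
    return 100.0 * num / den, False


def sensitivity(gold: CaseSet, billing: set[str]) -> ConcordanceResult:
    """Sensitivity of billing codes against the case-definition gold standard:
    100 * |gold ∩ billing| / |gold|, undefined (flagged) when no gold cases."""
    gold_ids = gold.case_ids
    overlap = gold_ids & set(billing)
    pct, undef = _proportion(len(overlap), len(gold_ids))
    return ConcordanceResult(
        condition_id=gold.condition_id,
        n_gold=len(gold_ids),
        n_billing=len(billing),
        n_overlap=len(overlap),
        value_pct=pct,
        kind="sensitivity",
        undefined=undef,
    )


def _contingency_test(table: dict[str, tuple[int, int]]) -> StratumTest:
    """Chi-square of recorded/not-recorded by stratum (no continuity
    correction); strata with zero denominator are dropped."""
    cells = {k: v for k, v in table.items() if v[1] > 0}
    if len(cells) < 2:
        return StratumTest(None, None, None, table=table, undefined=True)
    mat = np.array([[num, den - num] for num, den in cells.values()], dtype=float)
    if mat[:, 0].sum() == 0 or mat[:, 1].sum() == 0:
        # every patient (un)recorded: the test is degenerate
        return StratumTest(None, None, None, table=table, undefined=True)
    stat, p, df, _ = stats.chi2_contingency(mat, correction=False)
    return StratumTest(float(stat), int(df), float(p), table=table)


def stratified_tests(
    members: pd.DataFrame,
    numerator_ids: set[str],
    age_groups: Sequence[tuple[int, int | None]] = DEFAULT_AGE_GROUPS,
) -> tuple[StratumTest, StratumTest]:
    """Sex (2x2) and age-group (kx2) recorded-vs-not chi-squares."""
    recorded = members["patient_id"].isin(numerator_ids)
    sex_table: dict[str, tuple[int, int]] = {}
    for sex, g in members.groupby(members["sex"].astype(str)):
        sex_table[sex] = (int(recorded[g.index].sum()), int(len(g)))
    age_table: dict[str, tuple[int, int]] = {}
    ages = members["index_age"]
    for lo, hi in age_groups:
        mask = ages >= lo if hi is None else (ages >= lo) & (ages <= hi)
        age_table[age_group_label(lo, hi)] = (
            int(recorded[mask].sum()),
            int(mask.sum()),
        )
    return _contingency_test(sex_table), _contingency_test(age_table)


def patients_with_record(extract: EmrExtract, table: str) -> set[str]:
    """Patients with at least one row in a record table."""
    return set(extract.table(table)["patient_id"].dropna())


def patients_with_vital(extract: EmrExtract, kind: str) -> set[str]:
    df = extract.vitals
    return set(df.loc[df["kind"] == kind, "patient_id"].dropna())


def patients_with_bp(extract: EmrExtract, lenient: bool = False) -> set[str]:
    """Patients with a blood-pressure recording.

    Strict (default): systolic and diastolic on the same date. Lenient:
    either component counts.
    """
    if lenient:
        return patients_with_vital(extract, "systolic_bp") | patients_with_vital(
            extract, "diastolic_bp"
        )
    wide = _vitals_pairs(extract, ("systolic_bp", "diastolic_bp"))
    if wide.empty:
        return set()
    both = wide["systolic_bp"].notna() & wide["diastolic_bp"].notna()
    return set(wide.loc[both, "patient_id"])


def consistency_of_capture(
    extract: EmrExtract, cohort: Cohort, recent_days: int = 365
) -> dict[str, RecordingResult]:
    """Three capture proportions: problem list, allergy record (the
    no-known-allergies marker counts) and medications among patients with a
    visit in the final ``recent_days`` of the window."""
    ids = set(cohort.patient_ids)
    results: dict[str, RecordingResult] = {}

    with_problem = patients_with_record(extract, "problems") & ids
    pct, undef = _proportion(len(with_problem), len(ids))
    results["problem_list"] = RecordingResult(
        "problem_list", len(with_problem), len(ids), pct, undef
    )

    # any allergy row counts, including the explicit "no known allergies" marker
    with_allergy = patients_with_record(extract, "allergies") & ids
    pct, undef = _proportion(len(with_allergy), len(ids))
    results["allergy_record"] = RecordingResult(
        "allergy_record", len(with_allergy), len(ids), pct, undef
    )

    end = pd.Timestamp(extract.window_end)
    start_recent = end - pd.Timedelta(days=recent_days)
    v = extract.visits
    recent = set(
        v.loc[(v["event_date"] >= start_recent) & (v["event_date"] <= end), "patient_id"]
    ) & ids
    with_med = patients_with_record(extract, "medications") & recent
    pct, undef = _proportion(len(with_med), len(recent))
    results["medications"] = RecordingResult(
        "medications", len(with_med), len(recent), pct, undef
    )
    return results


def vitals_recording(
    extract: EmrExtract,
    cohort: Cohort,
    kind: str,
    age_groups: Sequence[tuple[int, int | None]] = DEFAULT_AGE_GROUPS,
    lenient_bp: bool = False,
    adult_age: int = 18,
) -> RecordingResult:
    """Proportion of patients with >=1 recording of a vital sign.

    ``kind`` is one of ``bp`` (denominator restricted to index age >=
    ``adult_age``), ``height`` or ``weight`` (all ages). Sex and age-group
    chi-squares accompany the overall proportion.
    """
    members = cohort.members
    if kind == "bp":
        members = members[members["index_age"] >= adult_age]
        have = patients_with_bp(extract, lenient=lenient_bp)
    elif kind in ("height", "weight"):
        have = patients_with_vital(extract, kind)
    else:
        raise ValueError(f"unknown vitals kind {kind!r}")
    ids = set(members["patient_id"])
    num = have & ids
    pct, undef = _proportion(len(num), len(ids))
    if len(members):
        sex_test, age_test = stratified_tests(members, num, age_groups)
    else:
        sex_test = age_test = StratumTest(None, None, None, undefined=True)
    return RecordingResult(
        measure=f"{kind}_recording",
        numerator=len(num),
        denominator=len(ids),
        pct=pct,
        undefined=undef,
        sex_test=sex_test,
        age_test=age_test,
    )


def _bp_dates(extract: EmrExtract, lenient: bool = False) -> pd.DataFrame:
    """(patient_id, event_date) rows carrying a BP recording."""
    if lenient:
        df = extract.vitals
        sel = df[df["kind"].isin(["systolic_bp", "diastolic_bp"])]
        return sel[["patient_id", "event_date"]].drop_duplicates()
    wide = _vitals_pairs(extract, ("systolic_bp", "diastolic_bp"))
    if wide.empty:
        return pd.DataFrame(columns=["patient_id", "event_date"])
    both = wide["systolic_bp"].notna() & wide["diastolic_bp"].notna()
    return wide.loc[both, ["patient_id", "event_date"]]


def _anchored_fraction(
    records: pd.DataFrame,
    anchors: pd.Series,
    window_days: int,
    direction: str = "after",
) -> tuple[int, int]:
    """Patients with a record within ``window_days`` of their anchor date.

    ``direction='after'`` counts records in [anchor, anchor + window] (both
    ends inclusive); ``'before'`` counts [anchor - window, anchor].
    """
    den = int(anchors.notna().sum())
    if den == 0 or records.empty:
        return 0, den
    joined = records.merge(
        anchors.rename("anchor"), left_on="patient_id", right_index=True
    )
    delta = (joined["event_date"] - joined["anchor"]).dt.days
    if direction == "after":
        ok = (delta >= 0) & (delta <= window_days)
    else:
        ok = (delta >= -window_days) & (delta <= 0)
    return int(joined.loc[ok, "patient_id"].nunique()), den


def bp_among_requiring(
    extract: EmrExtract,
    diabetes_cases: CaseSet,
    hypertension_med_patients: Mapping[str, pd.Timestamp] | pd.Series,
    window_days: int = 365,
    lenient_bp: bool = False,
) -> dict[str, RecordingResult]:
    """BP recording among patients who should be monitored.

    Two proportions: diabetes cases with >=1 BP within ``window_days`` after
    the diabetes onset date, and patients on hypertension medications (two
    or more oral anti-hypertensives, or one or more diuretics) with >=1 BP
    within ``window_days`` after the hypertension onset date. The window is
    the year *following* onset — monitoring follows diagnosis.
    """
    bp = _bp_dates(extract, lenient=lenient_bp)
    out: dict[str, RecordingResult] = {}

    onsets = diabetes_cases.onsets()
    if onsets.isna().any():
        raise AssertionError("diabetes case without onset date")
    num, den = _anchored_fraction(bp, onsets, window_days, "after")
    pct, undef = _proportion(num, den)
    out["diabetes"] = RecordingResult("bp_after_diabetes_onset", num, den, pct, undef)

    anchors = pd.Series(dict(hypertension_med_patients), dtype="datetime64[ns]")
    num, den = _anchored_fraction(bp, anchors, window_days, "after")
    pct, undef = _proportion(num, den)
    out["hypertension_medication"] = RecordingResult(
        "bp_after_hypertension_med", num, den, pct, undef
    )
    return out
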