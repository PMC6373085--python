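"""Declarative case definitions: identify condition cases and onset dates.

A case definition is a disjunction of clauses over problem-list terms,
medications, laboratory results, blood-pressure readings and BMI derived
from paired height/weight. A patient is a case if any clause is satisfied;
the onset date is the earliest record contributing to a satisfied clause.
Definitions live in editable YAML — thresholds and term lists are
configuration, because what counts as a "case" is a fitness-for-purpose
decision that each data user must be able to revise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .model import Cohort, EmrExtract, _completed_years

__all__ = [
    "DefinitionError",
    "CaseDefinition",
    "CaseSet",
    "normalize_term",
    "load_synonyms",
    "load_definitions",
    "default_definitions_path",
    "evaluate",
    "identify_cases",
    "billing_positives",
]

CONDITIONS = (
    "diabetes",
    "hypertension",
    "hypothyroidism",
    "asthma",
    "obesity",
    "urinary_tract_infection",
)


class DefinitionError(ValueError):
    """Raised for invalid case definitions (no clauses, unit mismatches...)."""


_WS = re.compile(r"[^a-z0-9%]+")


def _norm_basic(text: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return ""
    return " ".join(_WS.sub(" ", str(text).lower()).split())


@lru_cache(maxsize=4)
def _synonym_map(path: str | None) -> dict[str, str]:
    if path is None:
        source = resources.files("emrdq.data").joinpath("synonyms.yaml").read_text()
    else:
        source = Path(path).read_text()
    raw = yaml.safe_load(source) or {}
    mapping: dict[str, str] = {}
    for canonical, variants in raw.items():
        mapping[_norm_basic(canonical)] = canonical
        for v in variants or []:
            mapping[_norm_basic(v)] = canonical
    return mapping


def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Normalized-variant → canonical-token dictionary (shipped default)."""
    return dict(_synonym_map(str(path) if path is not None else None))


def normalize_term(text: str, synonyms: Mapping[str, str] | None = None) -> str:
    """Normalize a free-text term and map it through the synonym dictionary.

    Unknown terms come back as their basic normalization, so matching
    degrades gracefully to exact normalized-string comparison.
    """
    basic = _norm_basic(text)
    table = synonyms if synonyms is not None else _synonym_map(None)
    return table.get(basic, basic)


# ---------------------------------------------------------------------------
# clause types


@dataclass(frozen=True)
class ProblemTermClause:
    terms: tuple[str, ...]
    codes: tuple[str, ...] = ()


@dataclass(frozen=True)
class MedicationClause:
    names: tuple[str, ...] = ()
    class_codes: tuple[str, ...] = ()
    min_distinct: int = 1


@dataclass(frozen=True)
class LabClause:
    test_code: str
    comparator: str | None = None  # one of >=, >, <=, <, ==
    threshold: float | None = None
    units: str | None = None
    qualitative: str | None = None  # "positive" / "negative"


@dataclass(frozen=True)
class BmiClause:
    threshold: float = 30.0
    max_pair_gap_days: int = 0  # 0 = strict same-day pairing


@dataclass(frozen=True)
class BpClause:
    systolic: float = 140.0
    diastolic: float = 90.0
    min_count: int = 2
    distinct_dates: bool = True


@dataclass(frozen=True)
class ComboClause:
    """Qualitative lab result plus a medication within a trailing window."""

    lab: LabClause
    medications: MedicationClause
    window_days: int = 14


Clause = ProblemTermClause | MedicationClause | LabClause | BmiClause | BpClause | ComboClause

#: extract tables each clause type reads (used to degrade definitions when
#: an extract is missing a table)
CLAUSE_TABLES: dict[type, tuple[str, ...]] = {
    ProblemTermClause: ("problems",),
    MedicationClause: ("medications",),
    LabClause: ("labs",),
    BmiClause: ("vitals",),
    BpClause: ("vitals",),
    ComboClause: ("labs", "medications"),
}


@dataclass
class CaseDefinition:
    condition_id: str
    clauses: list[Clause]
    age_min: int | None = None
    age_max: int | None = None

    def __post_init__(self) -> None:
        if not self.clauses:
            raise DefinitionError(f"{self.condition_id}: definition needs at least one clause")

    def required_tables(self) -> set[str]:
        out: set[str] = set()
        for c in self.clauses:
            out.update(CLAUSE_TABLES[type(c)])
        return out

    def restrict_to_tables(self, available: Iterable[str]) -> tuple["CaseDefinition", list[str]]:
        """Drop clauses whose tables are unavailable; report what was dropped."""
        avail = set(available)
        kept, dropped = [], []
        for c in self.clauses:
            if set(CLAUSE_TABLES[type(c)]) <= avail:
                kept.append(c)
            else:
                dropped.append(type(c).__name__)
        if not kept:
            raise DefinitionError(
                f"{self.condition_id}: no clause evaluable with tables {sorted(avail)}"
            )
        return CaseDefinition(self.condition_id, kept, self.age_min, self.age_max), dropped


@dataclass
class CaseSet:
    """Per-patient case flags and onset dates for one condition."""

    condition_id: str
    table: pd.DataFrame  # columns: patient_id, is_case, onset_date

    @property
    def case_ids(self) -> set[str]:
        return set(self.table.loc[self.table["is_case"].astype(bool), "patient_id"])

    @property
    def n_cases(self) -> int:
        return int(self.table["is_case"].astype(bool).sum())

    def onset(self, patient_id: str) -> pd.Timestamp | None:
        row = self.table[self.table["patient_id"] == patient_id]
        if row.empty or not bool(row["is_case"].iloc[0]):
            return None
        return row["onset_date"].iloc[0]

    def onsets(self) -> pd.Series:
        cases = self.table[self.table["is_case"].astype(bool)]
        return cases.set_index("patient_id")["onset_date"]


# ---------------------------------------------------------------------------
# YAML loading


def default_definitions_path() -> Path:
    return Path(str(resources.files("emrdq.data").joinpath("default_definitions.yaml")))


def _parse_clause(spec: Mapping) -> Clause:
    if "problem_terms" in spec:
        return ProblemTermClause(
            terms=tuple(normalize_term(t) for t in spec["problem_terms"]),
            codes=tuple(str(c).strip() for c in spec.get("problem_codes", [])),
        )
    if "medications" in spec:
        m = spec["medications"]
        return MedicationClause(
            names=tuple(_norm_basic(n) for n in m.get("names", [])),
            class_codes=tuple(str(c).strip() for c in m.get("class_codes", [])),
            min_distinct=int(m.get("min_distinct", 1)),
        )
    if "lab" in spec:
        l = spec["lab"]
        return LabClause(
            test_code=str(l["test_code"]),
            comparator=l.get("comparator"),
            threshold=None if l.get("threshold") is None else float(l["threshold"]),
            units=l.get("units"),
            qualitative=l.get("qualitative"),
        )
    if "bmi" in spec:
        b = spec["bmi"]
        return BmiClause(
            threshold=float(b.get("threshold", 30.0)),
            max_pair_gap_days=int(b.get("max_pair_gap_days", 0)),
        )
    if "bp" in spec:
        b = spec["bp"]
        return BpClause(
            systolic=float(b.get("systolic", 140.0)),
            diastolic=float(b.get("diastolic", 90.0)),
            min_count=int(b.get("min_count", 2)),
            distinct_dates=bool(b.get("distinct_dates", True)),
        )
    if "lab_med_combo" in spec:
        c = spec["lab_med_combo"]
        lab = c["lab"]
        meds = c["medications"]
        return ComboClause(
            lab=LabClause(
                test_code=str(lab["test_code"]),
                qualitative=lab.get("qualitative", "positive"),
            ),
            medications=MedicationClause(
                names=tuple(_norm_basic(n) for n in meds.get("names", [])),
                class_codes=tuple(str(c_).strip() for c_ in meds.get("class_codes", [])),
                min_distinct=int(meds.get("min_distinct", 1)),
            ),
            window_days=int(c.get("window_days", 14)),
        )
    raise DefinitionError(f"unrecognized clause specification: {dict(spec)}")


def load_definitions(
    path: str | Path | None = None,
) -> tuple[dict[str, CaseDefinition], dict[str, list[str]]]:
    """Load (definitions, billing code map) from YAML; shipped defaults if None."""
    source = Path(path) if path is not None else default_definitions_path()
    doc = yaml.safe_load(source.read_text()) or {}
    defs: dict[str, CaseDefinition] = {}
    for cond, spec in (doc.get("definitions") or {}).items():
        clauses = [_parse_clause(c) for c in spec.get("clauses") or []]
        defs[cond] = CaseDefinition(
            condition_id=cond,
            clauses=clauses,
            age_min=spec.get("age_min"),
            age_max=spec.get("age_max"),
        )
    billing = {
        cond: [str(c).strip() for c in codes]
        for cond, codes in (doc.get("billing_codes") or {}).items()
    }
    return defs, billing


# ---------------------------------------------------------------------------
# clause matching (each returns a DataFrame of qualifying patient_id/event_date)


def _norm_series(values: pd.Series, with_synonyms: bool) -> pd.Series:
    uniq = values.dropna().unique()
    if with_synonyms:
        table = {u: normalize_term(u) for u in uniq}
    else:
        table = {u: _norm_basic(u) for u in uniq}
    return values.map(table)


def _match_problems(extract: EmrExtract, clause: ProblemTermClause) -> pd.DataFrame:
    df = extract.table("problems")
    if df.empty:
        return df[["patient_id", "event_date"]]
    tokens = _norm_series(df["text"], with_synonyms=True)
    hit = tokens.isin(clause.terms)
    if clause.codes:
        codes = df["code"].astype("string").str.strip()
        hit = hit | codes.isin(clause.codes)
    return df.loc[hit, ["patient_id", "event_date"]]


def _medication_name_match(names: pd.Series, clause_names: tuple[str, ...]) -> pd.Series:
    """A medication row matches if its normalized name equals, or starts
    with, a clause name (so "metformin 500 mg" matches "metformin")."""
    norm = _norm_series(names, with_synonyms=False)
    uniq = norm.dropna().unique()
    matched = {}
    for u in uniq:
        matched[u] = next(
            (c for c in clause_names if u == c or u.startswith(c + " ")), None
        )
    return norm.map(matched)


def _match_medications(extract: EmrExtract, clause: MedicationClause) -> pd.DataFrame:
    df = extract.table("medications")
    if df.empty:
        return df[["patient_id", "event_date"]]
    which = pd.Series(pd.NA, index=df.index, dtype="object")
    if clause.names:
        which = _medication_name_match(df["name"], clause.names)
    if clause.class_codes:
        codes = df["class_code"].astype("string").str.strip()
        by_code = pd.Series(pd.NA, index=df.index, dtype="object")
        for prefix in clause.class_codes:
            by_code = by_code.mask(codes.str.startswith(prefix, na=False), prefix)
        which = which.fillna(by_code)
    rows = df[which.notna()].copy()
    if rows.empty:
        return rows[["patient_id", "event_date"]]
    rows["_drug"] = which[which.notna()]
    if clause.min_distinct > 1:
        distinct = rows.groupby("patient_id")["_drug"].nunique()
        ok = set(distinct[distinct >= clause.min_distinct].index)
        rows = rows[rows["patient_id"].isin(ok)]
    return rows[["patient_id", "event_date"]]


_COMPARATORS = {
    ">=": lambda v, t: v >= t,
    ">": lambda v, t: v > t,
    "<=": lambda v, t: v <= t,
    "<": lambda v, t: v < t,
    "==": lambda v, t: v == t,
}


def _match_labs(extract: EmrExtract, clause: LabClause) -> pd.DataFrame:
    df = extract.table("labs")
    if df.empty:
        return df[["patient_id", "event_date"]]
    sel = df[df["test_code"].astype("string").str.strip() == clause.test_code]
    if sel.empty:
        return sel[["patient_id", "event_date"]]
    if clause.qualitative is not None:
        qual = sel["qualitative"].astype("string").str.strip().str.lower()
        return sel.loc[qual == clause.qualitative.lower(), ["patient_id", "event_date"]]
    if clause.comparator is None or clause.threshold is None:
        raise DefinitionError(f"lab clause for {clause.test_code} needs comparator+threshold")
    if clause.units is not None:
        units = sel["units"].astype("string").str.strip()
        mismatch = units.notna() & (units.str.lower() != clause.units.lower())
        if mismatch.any():
            raise DefinitionError(
                f"lab clause {clause.test_code}: units mismatch "
                f"(expected {clause.units!r}, saw {sorted(units[mismatch].unique())})"
            )
    cmp = _COMPARATORS.get(clause.comparator)
    if cmp is None:
        raise DefinitionError(f"unknown comparator {clause.comparator!r}")
    ok = cmp(sel["value"], clause.threshold)
    return sel.loc[ok.fillna(False), ["patient_id", "event_date"]]


def _height_metres(values: pd.Series, units: pd.Series) -> pd.Series:
    u = units.astype("string").str.strip().str.lower()
    cm = (u == "cm") | (u.isna() & (values > 3))
    return values.where(~cm, values / 100.0)


def _vitals_pairs(extract: EmrExtract, kinds: tuple[str, str]) -> pd.DataFrame:
    """Wide frame of same-day (patient, date) rows for two vitals kinds."""
    df = extract.table("vitals")
    if df.empty:
        return pd.DataFrame(columns=["patient_id", "event_date", kinds[0], kinds[1]])
    sel = df[df["kind"].isin(kinds)]
    if sel.empty:
        return pd.DataFrame(columns=["patient_id", "event_date", kinds[0], kinds[1]])
    wide = sel.pivot_table(
        index=["patient_id", "event_date"], columns="kind", values="value", aggfunc="max"
    ).reset_index()
    for k in kinds:
        if k not in wide.columns:
            wide[k] = pd.NA
    return wide


def _match_bmi(extract: EmrExtract, clause: BmiClause) -> pd.DataFrame:
    df = extract.table("vitals")
    empty = pd.DataFrame({"patient_id": pd.Series(dtype="string"),
                          "event_date": pd.Series(dtype="datetime64[ns]")})
    if df.empty:
        return empty
    heights = df[df["kind"] == "height"].copy()
    weights = df[df["kind"] == "weight"].copy()
    if heights.empty or weights.empty:
        return empty
    heights["height_m"] = _height_metres(heights["value"], heights["units"])
    if clause.max_pair_gap_days == 0:
        pair = weights.merge(
            heights[["patient_id", "event_date", "height_m"]],
            on=["patient_id", "event_date"],
        )
    else:
        tol = pd.Timedelta(days=clause.max_pair_gap_days)
        pair = pd.merge_asof(
            weights.sort_values("event_date"),
            heights[["patient_id", "event_date", "height_m"]].sort_values("event_date"),
            on="event_date",
            by="patient_id",
            direction="nearest",
            tolerance=tol,
        ).dropna(subset=["height_m"])
    if pair.empty:
        return empty
    bmi = pair["value"] / pair["height_m"] ** 2
    return pair.loc[bmi >= clause.threshold, ["patient_id", "event_date"]]


def _match_bp(extract: EmrExtract, clause: BpClause) -> pd.DataFrame:
    wide = _vitals_pairs(extract, ("systolic_bp", "diastolic_bp"))
    if wide.empty:
        return pd.DataFrame({"patient_id": pd.Series(dtype="string"),
                             "event_date": pd.Series(dtype="datetime64[ns]")})
    sys = pd.to_numeric(wide["systolic_bp"], errors="coerce")
    dia = pd.to_numeric(wide["diastolic_bp"], errors="coerce")
    high = (sys >= clause.systolic) | (dia >= clause.diastolic)
    rows = wide.loc[high.fillna(False), ["patient_id", "event_date"]]
    if clause.min_count > 1:
        counts = (
            rows.drop_duplicates() if clause.distinct_dates else rows
        ).groupby("patient_id").size()
        ok = set(counts[counts >= clause.min_count].index)
        rows = rows[rows["patient_id"].isin(ok)]
    return rows


def _match_combo(extract: EmrExtract, clause: ComboClause) -> pd.DataFrame:
    labs = _match_labs(extract, clause.lab)
    meds = _match_medications(extract, clause.medications)
    if labs.empty or meds.empty:
        return labs.iloc[0:0]
    joined = labs.merge(meds, on="patient_id", suffixes=("_lab", "_med"))
    delta = (joined["event_date_med"] - joined["event_date_lab"]).dt.days
    ok = (delta >= 0) & (delta <= clause.window_days)
    out = joined.loc[ok, ["patient_id", "event_date_lab"]]
    return out.rename(columns={"event_date_lab": "event_date"})


_MATCHERS = {
    ProblemTermClause: _match_problems,
    MedicationClause: _match_medications,
    LabClause: _match_labs,
    BmiClause: _match_bmi,
    BpClause: _match_bp,
    ComboClause: _match_combo,
}


# ---------------------------------------------------------------------------
# public evaluation API


def identify_cases(
    extract: EmrExtract, definition: CaseDefinition, cohort: Cohort
) -> CaseSet:
    """Evaluate a definition over the whole cohort (vectorized).

    Returns a :class:`CaseSet` with one row per cohort member; onset is the
    earliest record date contributing to any satisfied clause.
    """
    frames = []
    for clause in definition.clauses:
        hit = _MATCHERS[type(clause)](extract, clause)
        if not hit.empty:
            frames.append(hit)
    members = cohort.members
    eligible = pd.Series(True, index=members.index)
    if definition.age_min is not None:
        eligible &= members["index_age"] >= definition.age_min
    if definition.age_max is not None:
        eligible &= members["index_age"] <= definition.age_max
    eligible_ids = set(members.loc[eligible, "patient_id"])
    if frames:
        hits = pd.concat(frames, ignore_index=True)
        hits = hits[hits["patient_id"].isin(eligible_ids)]
        onset = hits.groupby("patient_id")["event_date"].min()
    else:
        onset = pd.Series(dtype="datetime64[ns]")
    table = pd.DataFrame(
        {
            "patient_id": members["patient_id"],
            "is_case": members["patient_id"].isin(onset.index).to_numpy(),
            "onset_date": members["patient_id"].map(onset),
        }
    )
    return CaseSet(condition_id=definition.condition_id, table=table.reset_index(drop=True))


def evaluate(
    extract: EmrExtract,
    definition: CaseDefinition,
    patient_id: str,
    index_date: date | str | None = None,
) -> tuple[bool, pd.Timestamp | None]:
    """Per-patient evaluation: (is_case, onset date or None).

    Age restrictions use the index age at ``index_date`` (default: window
    start); a patient whose age cannot be computed fails any age-restricted
    definition.
    """
    pats = extract.patients
    row = pats[pats["patient_id"] == patient_id]
    if row.empty:
        raise KeyError(f"unknown patient_id {patient_id!r}")
    idx = pd.Timestamp(index_date if index_date is not None else extract.window_start)
    if definition.age_min is not None or definition.age_max is not None:
        birth = row["birth_date"].iloc[0]
        if pd.isna(birth):
            return False, None
        age = int(_completed_years(pd.Series([birth]), idx).iloc[0])
        if definition.age_min is not None and age < definition.age_min:
            return False, None
        if definition.age_max is not None and age > definition.age_max:
            return False, None
    sliced = extract.for_patient(patient_id)
    best: pd.Timestamp | None = None
    for clause in definition.clauses:
        hit = _MATCHERS[type(clause)](sliced, clause)
        if not hit.empty:
            first = hit["event_date"].min()
            if best is None or first < best:
                best = first
    return best is not None, best


def billing_positives(
    extract: EmrExtract,
    condition_id: str,
    code_map: Mapping[str, Sequence[str]],
    cohort: Cohort,
) -> set[str]:
    """Cohort members with at least one billing record in the condition's code set."""
    codes = code_map.get(condition_id)
    if not codes:
        raise DefinitionError(f"no billing codes configured for {condition_id}")
    df = extract.table("billing")
    if df.empty:
        return set()
    clean = df["code"].astype("string").str.strip()
    hit = df.loc[clean.isin({str(c).strip() for c in codes}), "patient_id"]
    return set(hit) & set(cohort.patient_ids)
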