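"""Relational EMR extract model: schemas, I/O, validation and cohort utilities.

An extract is a snapshot of one practice database over a fixed observation
window, stored as nine delimited tables linked by an opaque patient
identifier. The model deliberately stores birth dates (not ages) so both the
index age and the age at any event are derivable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_SCHEMAS",
    "RECORD_TABLES",
    "NO_KNOWN_ALLERGIES",
    "VITALS_KINDS",
    "ExtractValidationError",
    "EmrExtract",
    "Cohort",
    "load_extract",
    "write_extract",
    "validate_extract",
    "extracts_equal",
    "complete_case_cohort",
    "last_visit_date",
    "age_at",
    "age_band",
    "age_band_labels",
    "assign_age_bands",
]

NO_KNOWN_ALLERGIES = "no known allergies"

VITALS_KINDS = ("systolic_bp", "diastolic_bp", "height", "weight")

#: required columns per table; ``event_date`` columns are parsed as dates.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_date"],
    "visits": ["patient_id", "event_date"],
    "problems": ["patient_id", "event_date", "text", "code"],
    "medications": ["patient_id", "event_date", "name", "class_code"],
    "labs": ["patient_id", "event_date", "test_code", "value", "units", "qualitative"],
    "vitals": ["patient_id", "event_date", "kind", "value", "units"],
    "billing": ["patient_id", "event_date", "code"],
    "immunizations": ["patient_id", "event_date", "vaccine"],
    "allergies": ["patient_id", "event_date", "substance"],
}

#: columns that may be absent in an input file (filled with NA on load)
OPTIONAL_COLUMNS: dict[str, set[str]] = {
    "problems": {"code"},
    "medications": {"class_code"},
    "labs": {"units", "qualitative"},
}

RECORD_TABLES = tuple(t for t in TABLE_SCHEMAS if t != "patients")

_NUMERIC_COLUMNS = {"labs": ["value"], "vitals": ["value"]}


class ExtractValidationError(ValueError):
    """Raised when an extract violates its schema or integrity rules.

    ``errors`` holds one human-readable message per offending row or column,
    each carrying the table name and (where applicable) the 1-based data row
    number in the source file.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        preview = "; ".join(self.errors[:5])
        more = "" if len(self.errors) <= 5 else f" (+{len(self.errors) - 5} more)"
        super().__init__(f"{len(self.errors)} extract validation error(s): {preview}{more}")


@dataclass
class EmrExtract:
    """Validated multi-table EMR snapshot plus its observation window."""

    tables: dict[str, pd.DataFrame]
    window_start: date
    window_end: date
    dialect: str = "structured"
    missing_tables: frozenset[str] = frozenset()
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ExtractValidationError(
                [f"window_start {self.window_start} is not before window_end {self.window_end}"]
            )
        for name in TABLE_SCHEMAS:
            if name not in self.tables:
                self.tables[name] = empty_table(name)
                if name != "patients":
                    self.missing_tables = self.missing_tables | {name}

    @property
    def patients(self) -> pd.DataFrame:
        return self.tables["patients"]

    @property
    def visits(self) -> pd.DataFrame:
        return self.tables["visits"]

    @property
    def vitals(self) -> pd.DataFrame:
        return self.tables["vitals"]

    @property
    def labs(self) -> pd.DataFrame:
        return self.tables["labs"]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def table(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def has_table(self, name: str) -> bool:
        return name not in self.missing_tables

    def for_patient(self, patient_id: str) -> "EmrExtract":
        """Slice every table down to one patient (no re-validation)."""
        sliced = {
            name: df[df["patient_id"] == patient_id].reset_index(drop=True)
            for name, df in self.tables.items()
        }
        return dataclasses.replace(self, tables=sliced, log=[])


def empty_table(name: str) -> pd.DataFrame:
    cols = TABLE_SCHEMAS[name]
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
    for c in cols:
        if c.endswith("_date"):
            df[c] = pd.Series(dtype="datetime64[ns]")
    for c in _NUMERIC_COLUMNS.get(name, []):
        df[c] = pd.Series(dtype="float64")
    return df


def _as_date(value: date | str | pd.Timestamp) -> date:
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, str):
        return pd.Timestamp(value).date()
    return value


def _parse_table(
    name: str, df: pd.DataFrame, *, source: str, errors: list[str], log: list[str]
) -> pd.DataFrame:
    required = [
        c for c in TABLE_SCHEMAS[name] if c not in OPTIONAL_COLUMNS.get(name, set())
    ]
    missing_cols = [c for c in required if c not in df.columns]
    if name == "patients" and "birth_date" in missing_cols and "age" in df.columns:
        missing_cols.remove("birth_date")
    if missing_cols:
        errors.append(f"{name}: missing required column(s) {missing_cols} in {source}")
        return empty_table(name)
    df = df.copy()
    for c in OPTIONAL_COLUMNS.get(name, set()):
        if c not in df.columns:
            df[c] = pd.NA
    date_cols = [c for c in TABLE_SCHEMAS[name] if c.endswith("_date") and c in df.columns]
    for c in date_cols:
        parsed = pd.to_datetime(df[c], errors="coerce", format="ISO8601")
        bad = df[c].notna() & parsed.isna()
        if name == "patients" and c == "birth_date":
            # missing birth dates are legal; only unparseable non-empty values fail
            pass
        for i in df.index[bad]:
            errors.append(f"{name} row {i + 1}: unparseable date {df.at[i, c]!r} in {c}")
        df[c] = parsed
    if name == "patients":
        if "birth_date" not in df.columns:
            # integer-age dialect: impute a mid-year birth date, flagged
            age = pd.to_numeric(df["age"], errors="coerce")
            df["birth_date"] = pd.NaT
            df["birth_date_imputed"] = age.notna()
            log.append(f"patients: birth_date imputed from integer age for {int(age.notna().sum())} rows")
            df["_age_for_imputation"] = age
        sex = df["sex"].astype("string").str.strip().str.lower()
        sex = sex.where(sex.isin(["male", "female"]), pd.NA)
        df["sex"] = sex
    for c in _NUMERIC_COLUMNS.get(name, []):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df["patient_id"] = df["patient_id"].astype("string")
    return df[list(dict.fromkeys(list(TABLE_SCHEMAS[name]) + [c for c in df.columns if c.startswith("birth_date_") or c.startswith("_")]))]


def validate_extract(extract: EmrExtract) -> None:
    """Check referential integrity, window bounds and value invariants.

    Raises :class:`ExtractValidationError` listing every offending row.
    Duplicate rows (identical across all columns) are dropped with a logged
    count rather than treated as errors.
    """
    errors: list[str] = []
    patients = extract.tables["patients"]
    dup_pat = patients["patient_id"].duplicated()
    for i in patients.index[dup_pat]:
        errors.append(f"patients row {i + 1}: duplicate patient_id {patients.at[i, 'patient_id']!r}")
    known = set(patients["patient_id"].dropna())
    end = pd.Timestamp(extract.window_end)
    for name in RECORD_TABLES:
        df = extract.tables[name]
        if df.empty:
            continue
        dups = df.duplicated()
        if dups.any():
            extract.tables[name] = df = df[~dups].reset_index(drop=True)
            extract.log.append(f"{name}: dropped {int(dups.sum())} duplicate row(s)")
        orphan = ~df["patient_id"].isin(known)
        for i in df.index[orphan]:
            errors.append(
                f"{name} row {i + 1}: patient_id {df.at[i, 'patient_id']!r} not in patients table"
            )
        late = df["event_date"].notna() & (df["event_date"] > end)
        for i in df.index[late]:
            errors.append(f"{name} row {i + 1}: event_date {df.at[i, 'event_date'].date()} after window end")
        nodate = df["event_date"].isna()
        for i in df.index[nodate]:
            errors.append(f"{name} row {i + 1}: missing event_date")
    vit = extract.tables["vitals"]
    if not vit.empty:
        bad_kind = ~vit["kind"].isin(VITALS_KINDS)
        for i in vit.index[bad_kind]:
            errors.append(f"vitals row {i + 1}: unknown kind {vit.at[i, 'kind']!r}")
        nonpos = vit["value"].isna() | (vit["value"] <= 0)
        for i in vit.index[nonpos]:
            errors.append(f"vitals row {i + 1}: value must be strictly positive")
    if errors:
        raise ExtractValidationError(errors)


def load_extract(
    source: str | Path | Mapping[str, str | Path],
    window: tuple[date | str, date | str] | None = None,
    dialect: str | None = None,
) -> EmrExtract:
    """Read per-table CSVs into a validated :class:`EmrExtract`.

    ``source`` is either a directory holding ``patients.csv`` etc. (and
    optionally a ``manifest.json`` with the window and dialect, as written by
    :func:`write_extract`) or an explicit table→path mapping. Tables other
    than ``patients`` may be absent; they load as empty and are recorded in
    ``missing_tables`` so downstream measures can report themselves
    not-computable instead of silently returning zeros.
    """
    errors: list[str] = []
    log: list[str] = []
    if isinstance(source, (str, Path)):
        directory = Path(source)
        paths: dict[str, Path] = {t: directory / f"{t}.csv" for t in TABLE_SCHEMAS}
        manifest = directory / "manifest.json"
        if manifest.exists():
            meta = json.loads(manifest.read_text())
            if window is None:
                window = (meta["window_start"], meta["window_end"])
            if dialect is None:
                dialect = meta.get("dialect")
    else:
        paths = {t: Path(p) for t, p in source.items()}
    if window is None:
        raise ValueError("window must be given explicitly or via manifest.json")
    dialect = dialect or "structured"

    tables: dict[str, pd.DataFrame] = {}
    missing: set[str] = set()
    for name in TABLE_SCHEMAS:
        path = paths.get(name)
        if path is None or not Path(path).exists():
            if name == "patients":
                raise ExtractValidationError([f"patients table not found at {path}"])
            missing.add(name)
            tables[name] = empty_table(name)
            log.append(f"{name}: table file absent, treated as missing")
            continue
        raw = pd.read_csv(path, dtype="object", keep_default_na=True)
        tables[name] = _parse_table(name, raw, source=str(path), errors=errors, log=log)
    if errors:
        raise ExtractValidationError(errors)

    extract = EmrExtract(
        tables=tables,
        window_start=_as_date(window[0]),
        window_end=_as_date(window[1]),
        dialect=dialect,
        missing_tables=frozenset(missing),
        log=log,
    )
    _impute_birth_dates(extract)
    validate_extract(extract)
    return extract


def _impute_birth_dates(extract: EmrExtract) -> None:
    pats = extract.tables["patients"]
    if "_age_for_imputation" in pats.columns:
        age = pats["_age_for_imputation"]
        ok = age.notna() & (age >= 0)
        # mid-year convention: age-years plus half a year before the window
        # start, so the completed age at the window start equals the input
        days = (age[ok].astype(int) * 365.2425).round().astype(int) + 183
        pats.loc[ok, "birth_date"] = (
            pd.Timestamp(extract.window_start) - pd.to_timedelta(days, unit="D")
        ).values
        pats.drop(columns=["_age_for_imputation"], inplace=True)


def write_extract(extract: EmrExtract, directory: str | Path) -> Path:
    """Write the nine CSVs plus a manifest.json; inverse of :func:`load_extract`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, df in extract.tables.items():
        if name in extract.missing_tables:
            continue
        out = df.copy()
        for c in out.columns:
            if c.endswith("_date"):
                out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
        out = out[[c for c in out.columns if not c.startswith("_")]]
        out.to_csv(directory / f"{name}.csv", index=False)
    (directory / "manifest.json").write_text(
        json.dumps(
            {
                "window_start": extract.window_start.isoformat(),
                "window_end": extract.window_end.isoformat(),
                "dialect": extract.dialect,
            },
            indent=2,
        )
    )
    return directory


def extracts_equal(a: EmrExtract, b: EmrExtract) -> bool:
    """Field-for-field equality over windows, dialect and table contents."""
    if (a.window_start, a.window_end, a.dialect) != (b.window_start, b.window_end, b.dialect):
        return False
    for name in TABLE_SCHEMAS:
        ta = a.tables[name][TABLE_SCHEMAS[name]].reset_index(drop=True)
        tb = b.tables[name][TABLE_SCHEMAS[name]].reset_index(drop=True)
        # normalize null-likes (None vs NaN) so equality is value-based
        ta = ta.apply(lambda s: s.where(s.notna(), pd.NA) if s.dtype == object else s)
        tb = tb.apply(lambda s: s.where(s.notna(), pd.NA) if s.dtype == object else s)
        if len(ta) != len(tb):
            return False
        order = [c for c in ta.columns]
        ta = ta.sort_values(order, kind="stable").reset_index(drop=True)
        tb = tb.sort_values(order, kind="stable").reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(ta, tb, check_dtype=False)
        except AssertionError:
            return False
    return True


# ---------------------------------------------------------------------------
# cohort utilities


@dataclass
class Cohort:
    """Complete-case analysis population at a fixed index date.

    ``members`` has one row per included patient with columns
    ``patient_id``, ``sex`` and ``index_age`` (completed years at the index
    date). ``exclusions`` counts excluded patients by reason; each excluded
    patient is counted under exactly one reason.
    """

    members: pd.DataFrame
    index_date: date
    exclusions: dict[str, int]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def patient_ids(self) -> pd.Series:
        return self.members["patient_id"]

    def ages(self) -> pd.Series:
        return self.members["index_age"]

    def subset(self, patient_ids: Iterable[str]) -> "Cohort":
        keep = self.members["patient_id"].isin(set(patient_ids))
        return Cohort(self.members[keep].reset_index(drop=True), self.index_date, {})


def _completed_years(birth: pd.Series, at: pd.Series | pd.Timestamp) -> pd.Series:
    """Vectorized age in completed years (birthday-accurate, not /365.25)."""
    birth = pd.to_datetime(birth)
    if isinstance(at, pd.Timestamp):
        at = pd.Series([at] * len(birth), index=birth.index)
    at = pd.to_datetime(at)
    years = at.dt.year - birth.dt.year
    before_birthday = (at.dt.month < birth.dt.month) | (
        (at.dt.month == birth.dt.month) & (at.dt.day < birth.dt.day)
    )
    return years - before_birthday.astype(int)


def age_at(birth_date: date | str, when: date | str) -> int:
    """Age in completed years on ``when`` for a single birth date."""
    b = pd.Timestamp(birth_date)
    w = pd.Timestamp(when)
    return int(w.year - b.year - ((w.month, w.day) < (b.month, b.day)))


def complete_case_cohort(extract: EmrExtract, index_date: date | str | None = None) -> Cohort:
    """Patients with non-missing sex and a computable non-negative index age.

    The index date defaults to the extract window start, matching the
    convention of measuring age at the start of the observation window.
    """
    idx = pd.Timestamp(index_date if index_date is not None else extract.window_start)
    pats = extract.patients
    exclusions = {"missing_sex": 0, "missing_age": 0, "negative_age": 0}
    sex_ok = pats["sex"].notna()
    birth_ok = pats["birth_date"].notna()
    age = pd.Series(np.nan, index=pats.index, dtype="float64")
    if birth_ok.any():
        age.loc[birth_ok] = _completed_years(pats.loc[birth_ok, "birth_date"], idx).astype(float)
    nonneg = age >= 0
    include = sex_ok & birth_ok & nonneg
    exclusions["missing_sex"] = int((~sex_ok).sum())
    exclusions["missing_age"] = int((sex_ok & ~birth_ok).sum())
    exclusions["negative_age"] = int((sex_ok & birth_ok & ~nonneg).sum())
    members = pd.DataFrame(
        {
            "patient_id": pats.loc[include, "patient_id"].astype("string"),
            "sex": pats.loc[include, "sex"],
            "index_age": age[include].astype(int),
        }
    ).reset_index(drop=True)
    return Cohort(members=members, index_date=idx.date(), exclusions=exclusions)


def last_visit_date(extract: EmrExtract, patient_id: str) -> date | None:
    """Latest visit date on or before the window end, or None without visits."""
    pats = set(extract.patients["patient_id"].dropna())
    if patient_id not in pats:
        raise KeyError(f"unknown patient_id {patient_id!r}")
    v = extract.visits
    mine = v[(v["patient_id"] == patient_id) & (v["event_date"] <= pd.Timestamp(extract.window_end))]
    if mine.empty:
        return None
    return mine["event_date"].max().date()


def last_visit_series(extract: EmrExtract) -> pd.Series:
    """patient_id → last visit Timestamp for all patients with visits."""
    v = extract.visits
    v = v[v["event_date"] <= pd.Timestamp(extract.window_end)]
    return v.groupby("patient_id")["event_date"].max()


# ---------------------------------------------------------------------------
# age banding


def age_band_labels(band_width: int = 5, top_band_start: int = 85) -> list[str]:
    if band_width <= 0 or top_band_start % band_width != 0:
        raise ValueError("top_band_start must be a positive multiple of band_width")
    labels = [f"{lo}-{lo + band_width - 1}" for lo in range(0, top_band_start, band_width)]
    labels.append(f"{top_band_start}+")
    return labels


def age_band(index_age: int, band_width: int = 5, top_band_start: int = 85) -> str:
    """Half-open age band label: [0,w), [w,2w), ..., [top, inf)."""
    if index_age < 0:
        raise ValueError(f"age must be non-negative, got {index_age}")
    if index_age >= top_band_start:
        return f"{top_band_start}+"
    lo = (int(index_age) // band_width) * band_width
    return f"{lo}-{lo + band_width - 1}"


def assign_age_bands(
    ages: pd.Series | np.ndarray, band_width: int = 5, top_band_start: int = 85
) -> pd.Categorical:
    """Vectorized banding returning an ordered categorical over all labels."""
    ages = np.asarray(ages)
    if (ages < 0).any():
        raise ValueError("ages must be non-negative")
    labels = age_band_labels(band_width, top_band_start)
    idx = np.minimum(ages // band_width, len(labels) - 1).astype(int)
    return pd.Categorical.from_codes(idx, categories=labels, ordered=True)
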