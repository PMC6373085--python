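"""Shared fixtures: hand-built micro-extracts and cached synthetic runs."""

from __future__ import annotations

import pandas as pd
import pytest

from emrdq.cases import load_definitions
from emrdq.model import TABLE_SCHEMAS, EmrExtract, empty_table, validate_extract
from emrdq.synth import SynthConfig, generate

DEFAULT_WINDOW = ("2006-01-01", "2010-12-31")


def make_extract(window=DEFAULT_WINDOW, dialect="structured", validate=True, **tables):
    """Build an extract from lists of row dicts, e.g.
    make_extract(patients=[{"patient_id": "a", "sex": "male",
    "birth_date": "1970-06-01"}], visits=[...])."""
    built: dict[str, pd.DataFrame] = {}
    for name in TABLE_SCHEMAS:
        rows = tables.get(name)
        if not rows:
            built[name] = empty_table(name)
            continue
        df = pd.DataFrame(rows)
        for col in TABLE_SCHEMAS[name]:
            if col not in df.columns:
                df[col] = pd.NA
            if col.endswith("_date"):
                df[col] = pd.to_datetime(df[col])
        built[name] = df[TABLE_SCHEMAS[name]]
    extract = EmrExtract(
        tables=built,
        window_start=pd.Timestamp(window[0]).date(),
        window_end=pd.Timestamp(window[1]).date(),
        dialect=dialect,
    )
    if validate:
        validate_extract(extract)
    return extract


def patient(pid, sex="female", birth="1970-06-01"):
    return {"patient_id": pid, "sex": sex, "birth_date": birth}


@pytest.fixture(scope="session")
def definitions():
    defs, codes = load_definitions()
    return defs


@pytest.fixture(scope="session")
def billing_codes():
    _, codes = load_definitions()
    return codes


@pytest.fixture(scope="session")
def synth_small():
    """One moderate synthetic extract reused across read-only tests."""
    return generate(SynthConfig(n_patients=2000, seed=42))


@pytest.fixture(scope="session")
def synth_large():
    """One full-size synthetic extract for measure-level checks."""
    return generate(SynthConfig(n_patients=10_000, seed=202))
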