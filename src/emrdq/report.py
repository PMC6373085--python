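"""Four-domain assessment orchestration, small-cell suppression and rendering.

``run_assessment`` computes the eleven measure families over one extract and
returns a :class:`DqReport`. Measures that cannot be computed (a missing
table, a fully degraded case definition, an empty denominator) are present
in the report with machine-readable reasons — never silently omitted.

Suppression is render-only: the JSON report keeps exact counts behind the
``suppressed`` flag while CSV and markdown renderings withhold them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .cases import (
    CaseDefinition,
    CaseSet,
    DefinitionError,
    MedicationClause,
    _match_medications,
    billing_positives,
    identify_cases,
    load_definitions,
)
from .comparability import (
    StandardPopulation,
    age_sex_table,
    chi_square_vs_standard,
    mean_median_age,
    standardized_prevalence,
)
from .completeness import (
    DEFAULT_AGE_GROUPS,
    ConcordanceResult,
    RecordingResult,
    StratumTest,
    bp_among_requiring,
    consistency_of_capture,
    sensitivity,
    vitals_recording,
)
from .correctness_currency import (
    TimelinessResult,
    ppv,
    pregnancy_followup,
    unlikely_vaccination,
    vitals_timeliness,
    weight_timeliness_obesity,
)
from .model import Cohort, EmrExtract, complete_case_cohort

__all__ = [
    "DOMAINS",
    "MEASURE_FAMILIES",
    "MeasureResult",
    "DqReport",
    "run_assessment",
    "suppress_small_cells",
    "render",
    "round_half_up",
    "format_pct",
    "format_p",
]

DOMAINS = ("comparability", "completeness", "correctness", "currency")

#: the eleven measure families, in report order
MEASURE_FAMILIES: tuple[tuple[str, str], ...] = (
    ("comparability", "population_structure"),
    ("comparability", "condition_prevalence"),
    ("completeness", "sensitivity"),
    ("completeness", "consistency_of_capture"),
    ("completeness", "vitals_recording"),
    ("completeness", "bp_among_requiring"),
    ("correctness", "ppv"),
    ("correctness", "unlikely_vaccination"),
    ("currency", "weight_timeliness_obesity"),
    ("currency", "pregnancy_followup"),
    ("currency", "vitals_timeliness"),
)


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (0.05 -> 0.1), matching printed-table style."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(value: float | None) -> str:
    if value is None:
        return "undefined"
    return f"{round_half_up(value, 1):.1f}"


def format_p(p: float | None) -> str:
    if p is None:
        return ""
    if p < 0.001:
        return "<0.001"
    return f"{round_half_up(p, 3):.3f}"


@dataclass
class MeasureResult:
    domain: str
    family: str
    measure_id: str
    condition_id: str | None = None
    numerator: int | None = None
    denominator: int | None = None
    value_pct: float | None = None
    ci95: tuple[float, float] | None = None
    test: dict[str, Any] | None = None
    reference_pct: float | None = None
    extra: dict[str, Any] = field(default_factory=dict)
    suppressed: bool = False
    undefined: bool = False
    not_computable_reason: str | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.ci95 is not None:
            d["ci95"] = list(self.ci95)
        return d


@dataclass
class DqReport:
    results: list[MeasureResult]
    metadata: dict[str, Any]
    suppression_threshold: int | None = None

    def by_family(self, family: str) -> list[MeasureResult]:
        return [r for r in self.results if r.family == family]

    def family_status(self) -> dict[str, str]:
        """computed / not_computable(reason) per measure family."""
        status: dict[str, str] = {}
        for _, fam in MEASURE_FAMILIES:
            members = self.by_family(fam)
            if not members:
                status[fam] = "not_computable: absent"
            elif all(m.not_computable_reason for m in members):
                status[fam] = f"not_computable: {members[0].not_computable_reason}"
            else:
                status[fam] = "computed"
        return status

    def to_dict(self) -> dict[str, Any]:
        return {
            "metadata": self.metadata,
            "suppression_threshold": self.suppression_threshold,
            "family_status": self.family_status(),
            "results": [r.to_dict() for r in self.results],
        }


DEFAULT_CONFIG: dict[str, Any] = {
    "reference_prevalence": {},
    "windows": {
        "bp_followup_days": 365,
        "vitals_timeliness_days": 365,
        "pregnancy_followup_days": 62,
        "recent_visit_days": 365,
    },
    "age_groups": [list(g) for g in DEFAULT_AGE_GROUPS],
    "adult_age": 18,
    "suppression_threshold": 5,
    "sex_specific_standardization": True,
    "pregnancy_test_code": "pregnancy_hcg",
    "seed": None,
}


def _merge_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for k, v in (config or {}).items():
        if isinstance(v, Mapping) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _test_dict(t: StratumTest | None) -> dict[str, Any] | None:
    if t is None:
        return None
    return {
        "statistic": t.statistic,
        "df": t.df,
        "p": t.p,
        "table": {k: list(v) for k, v in t.table.items()},
        "undefined": t.undefined,
    }


def _from_recording(
    domain: str, family: str, r: RecordingResult, condition: str | None = None
) -> MeasureResult:
    return MeasureResult(
        domain=domain,
        family=family,
        measure_id=r.measure,
        condition_id=condition,
        numerator=r.numerator,
        denominator=r.denominator,
        value_pct=r.pct,
        undefined=r.undefined,
        test=None
        if r.sex_test is None and r.age_test is None
        else {"sex": _test_dict(r.sex_test), "age_group": _test_dict(r.age_test)},
    )


def _from_timeliness(domain: str, family: str, r: TimelinessResult) -> MeasureResult:
    m = MeasureResult(
        domain=domain,
        family=family,
        measure_id=r.measure,
        numerator=r.numerator,
        denominator=r.denominator,
        value_pct=r.pct,
        undefined=r.undefined,
        extra={"window_days": r.window_days, "excluded_no_visit": r.excluded_no_visit},
        test=None
        if r.sex_test is None and r.age_test is None
        else {"sex": _test_dict(r.sex_test), "age_group": _test_dict(r.age_test)},
    )
    return m


def _from_concordance(domain: str, family: str, r: ConcordanceResult) -> MeasureResult:
    return MeasureResult(
        domain=domain,
        family=family,
        measure_id=f"{r.kind}_{r.condition_id}",
        condition_id=r.condition_id,
        numerator=r.n_overlap,
        denominator=r.n_gold if r.kind == "sensitivity" else r.n_billing,
        value_pct=r.value_pct,
        undefined=r.undefined,
        extra={"n_gold": r.n_gold, "n_billing": r.n_billing, "n_overlap": r.n_overlap},
    )


def _not_computable(domain: str, family: str, measure_id: str, reason: str,
                    condition: str | None = None) -> MeasureResult:
    return MeasureResult(
        domain=domain,
        family=family,
        measure_id=measure_id,
        condition_id=condition,
        not_computable_reason=reason,
    )


def _hypertension_med_anchors(
    extract: EmrExtract,
    definition: CaseDefinition | None,
    htn_cases: CaseSet | None,
    cohort: Cohort,
) -> pd.Series:
    """Patients qualifying on the definition's medication clauses (two or
    more oral anti-hypertensives, or one or more diuretics), anchored at the
    hypertension onset date where known, else at the first qualifying
    prescription."""
    if definition is None:
        return pd.Series(dtype="datetime64[ns]")
    frames = []
    for clause in definition.clauses:
        if isinstance(clause, MedicationClause):
            hit = _match_medications(extract, clause)
            if not hit.empty:
                frames.append(hit)
    if not frames:
        return pd.Series(dtype="datetime64[ns]")
    hits = pd.concat(frames, ignore_index=True)
    hits = hits[hits["patient_id"].isin(set(cohort.patient_ids))]
    first_med = hits.groupby("patient_id")["event_date"].min()
    if htn_cases is not None:
        onsets = htn_cases.onsets()
        anchored = onsets.reindex(first_med.index)
        return anchored.fillna(first_med)
    return first_med


def run_assessment(
    extract: EmrExtract,
    definitions: Mapping[str, CaseDefinition] | None = None,
    standard: StandardPopulation | None = None,
    config: Mapping[str, Any] | None = None,
    billing_codes: Mapping[str, Sequence[str]] | None = None,
) -> DqReport:
    """Compute all eleven measure families over one extract.

    Definitions default to the shipped YAML; the standard population to the
    shipped synthetic pyramid. Measures whose inputs are unavailable carry
    ``not_computable_reason`` instead of being dropped.
    """
    cfg = _merge_config(config)
    if definitions is None or billing_codes is None:
        default_defs, default_codes = load_definitions()
        definitions = definitions if definitions is not None else default_defs
        billing_codes = billing_codes if billing_codes is not None else default_codes
    standard = standard if standard is not None else StandardPopulation.synthetic_default()
    age_groups = [tuple(g) for g in cfg["age_groups"]]
    adult_age = int(cfg["adult_age"])
    windows = cfg["windows"]

    cohort = complete_case_cohort(extract, cfg.get("index_date"))
    available = [t for t in extract.tables if extract.has_table(t)]
    results: list[MeasureResult] = []

    # --- comparability: population structure ------------------------------
    if len(cohort) == 0:
        results.append(
            _not_computable("comparability", "population_structure",
                            "age_sex_chi_square", "empty cohort")
        )
    else:
        table = age_sex_table(cohort)
        chi = chi_square_vs_standard(table, standard)
        ages = mean_median_age(cohort)
        results.append(
            MeasureResult(
                domain="comparability",
                family="population_structure",
                measure_id="age_sex_chi_square",
                test={"statistic": chi.statistic, "df": chi.df, "p": chi.p,
                      "pooled_cells": chi.pooled_cells},
                extra={
                    "counts": {str(b): {s: int(table.loc[b, s]) for s in table.columns}
                               for b in table.index},
                    "standard": standard.name,
                },
            )
        )
        results.append(
            MeasureResult(
                domain="comparability",
                family="population_structure",
                measure_id="mean_median_age",
                extra={"ages": ages},
            )
        )

    # --- case identification (shared by several families) -----------------
    case_sets: dict[str, CaseSet | None] = {}
    degraded_defs: dict[str, CaseDefinition | None] = {}
    definition_notes: dict[str, list[str]] = {}
    for cond, definition in definitions.items():
        try:
            usable, dropped = definition.restrict_to_tables(available)
        except DefinitionError as exc:
            case_sets[cond] = None
            degraded_defs[cond] = None
            definition_notes[cond] = [str(exc)]
            continue
        notes = [f"definition degraded: dropped {d} clause" for d in dropped]
        definition_notes[cond] = notes
        degraded_defs[cond] = usable
        case_sets[cond] = identify_cases(extract, usable, cohort) if len(cohort) else None

    # --- comparability: condition prevalence ------------------------------
    for cond, definition in definitions.items():
        cases = case_sets.get(cond)
        if cases is None or len(cohort) == 0:
            reason = (
                "empty cohort" if len(cohort) == 0
                else f"definition not evaluable: {definition_notes[cond][0]}"
            )
            results.append(
                _not_computable("comparability", "condition_prevalence",
                                f"prevalence_{cond}", reason, cond)
            )
            continue
        usable = degraded_defs[cond]
        ref = cfg["reference_prevalence"].get(cond)
        age_restricted = usable.age_min is not None or usable.age_max is not None
        sub = cohort
        if age_restricted:
            m = cohort.members
            keep = pd.Series(True, index=m.index)
            if usable.age_min is not None:
                keep &= m["index_age"] >= usable.age_min
            if usable.age_max is not None:
                keep &= m["index_age"] <= usable.age_max
            sub = Cohort(m[keep].reset_index(drop=True), cohort.index_date, {})
        if len(sub) == 0:
            results.append(
                _not_computable("comparability", "condition_prevalence",
                                f"prevalence_{cond}", "no patients in age range", cond)
            )
            continue
        if age_restricted:
            # crude only: standardization is not meaningful on a truncated
            # age range (the asthma convention)
            n_cases = len(cases.case_ids & set(sub.patient_ids))
            res = MeasureResult(
                domain="comparability",
                family="condition_prevalence",
                measure_id=f"prevalence_{cond}",
                condition_id=cond,
                numerator=n_cases,
                denominator=len(sub),
                value_pct=100.0 * n_cases / len(sub),
                reference_pct=ref,
                notes=definition_notes[cond] + ["crude only: age-restricted definition"],
            )
        else:
            prev = standardized_prevalence(
                cases, sub, standard,
                sex_specific=bool(cfg["sex_specific_standardization"]),
                reference_pct=ref,
            )
            res = MeasureResult(
                domain="comparability",
                family="condition_prevalence",
                measure_id=f"prevalence_{cond}",
                condition_id=cond,
                numerator=prev.n_cases,
                denominator=prev.n_cohort,
                value_pct=prev.crude_pct,
                ci95=prev.ci95,
                reference_pct=ref,
                extra={
                    "standardized_pct": prev.standardized_pct,
                    "ci_method": prev.ci_method,
                    "dropped_strata": prev.dropped_strata,
                },
                notes=definition_notes[cond],
            )
        results.append(res)

    # --- completeness: sensitivity / correctness: ppv ----------------------
    billing_ok = extract.has_table("billing")
    for cond in definitions:
        cases = case_sets.get(cond)
        if cases is None or not billing_ok or len(cohort) == 0:
            reason = (
                "billing table missing" if not billing_ok
                else "empty cohort" if len(cohort) == 0
                else f"definition not evaluable: {definition_notes[cond][0]}"
            )
            results.append(_not_computable("completeness", "sensitivity",
                                           f"sensitivity_{cond}", reason, cond))
            results.append(_not_computable("correctness", "ppv",
                                           f"ppv_{cond}", reason, cond))
            continue
        billed = billing_positives(extract, cond, billing_codes, cohort)
        sens = sensitivity(cases, billed)
        sens_res = _from_concordance("completeness", "sensitivity", sens)
        sens_res.notes = definition_notes[cond]
        results.append(sens_res)
        ppv_res = _from_concordance("correctness", "ppv", ppv(cases, billed))
        ppv_res.notes = definition_notes[cond]
        results.append(ppv_res)

    # --- completeness: consistency of capture ------------------------------
    cap_tables = {"problem_list": "problems", "allergy_record": "allergies",
                  "medications": "medications"}
    if len(cohort) == 0:
        for key in cap_tables:
            results.append(_not_computable("completeness", "consistency_of_capture",
                                           key, "empty cohort"))
    else:
        captured = consistency_of_capture(
            extract, cohort, recent_days=int(windows["recent_visit_days"])
        )
        for key, table_name in cap_tables.items():
            if not extract.has_table(table_name):
                results.append(_not_computable(
                    "completeness", "consistency_of_capture", key,
                    f"{table_name} table missing"))
            else:
                results.append(_from_recording("completeness",
                                               "consistency_of_capture", captured[key]))

    # --- completeness: vitals recording / currency: vitals timeliness ------
    vitals_ok = extract.has_table("vitals")
    visits_ok = extract.has_table("visits")
    for kind in ("bp", "height", "weight"):
        if not vitals_ok or len(cohort) == 0:
            reason = "vitals table missing" if not vitals_ok else "empty cohort"
            results.append(_not_computable("completeness", "vitals_recording",
                                           f"{kind}_recording", reason))
            results.append(_not_computable("currency", "vitals_timeliness",
                                           f"{kind}_timeliness", reason))
            continue
        results.append(_from_recording(
            "completeness", "vitals_recording",
            vitals_recording(extract, cohort, kind, age_groups=age_groups,
                             adult_age=adult_age),
        ))
        if not visits_ok:
            results.append(_not_computable("currency", "vitals_timeliness",
                                           f"{kind}_timeliness", "visits table missing"))
        else:
            results.append(_from_timeliness(
                "currency", "vitals_timeliness",
                vitals_timeliness(extract, cohort, kind,
                                  window_days=int(windows["vitals_timeliness_days"]),
                                  age_groups=age_groups, adult_age=adult_age),
            ))

    # --- completeness: BP among patients requiring it -----------------------
    dm_cases = case_sets.get("diabetes")
    htn_cases = case_sets.get("hypertension")
    if not vitals_ok or len(cohort) == 0:
        reason = "vitals table missing" if not vitals_ok else "empty cohort"
        results.append(_not_computable("completeness", "bp_among_requiring",
                                       "bp_after_diabetes_onset", reason, "diabetes"))
        results.append(_not_computable("completeness", "bp_among_requiring",
                                       "bp_after_hypertension_med", reason, "hypertension"))
    else:
        if dm_cases is None:
            results.append(_not_computable(
                "completeness", "bp_among_requiring", "bp_after_diabetes_onset",
                f"definition not evaluable: {definition_notes['diabetes'][0]}"
                if "diabetes" in definition_notes else "no diabetes definition",
                "diabetes"))
            dm_for_bp = CaseSet("diabetes", pd.DataFrame(
                {"patient_id": [], "is_case": [], "onset_date": []}))
        else:
            dm_for_bp = dm_cases
        anchors = _hypertension_med_anchors(
            extract, degraded_defs.get("hypertension"), htn_cases, cohort
        )
        bp_req = bp_among_requiring(
            extract, dm_for_bp, anchors,
            window_days=int(windows["bp_followup_days"]),
        )
        if dm_cases is not None:
            r = _from_recording("completeness", "bp_among_requiring",
                                bp_req["diabetes"], "diabetes")
            r.extra["window_days"] = int(windows["bp_followup_days"])
            results.append(r)
        r = _from_recording("completeness", "bp_among_requiring",
                            bp_req["hypertension_medication"], "hypertension")
        r.extra["window_days"] = int(windows["bp_followup_days"])
        results.append(r)

    # --- correctness: unlikely vaccination ---------------------------------
    if not extract.has_table("immunizations") or len(cohort) == 0:
        reason = ("immunizations table missing"
                  if not extract.has_table("immunizations") else "empty cohort")
        results.append(_not_computable("correctness", "unlikely_vaccination",
                                       "unlikely_vaccination", reason))
    else:
        results.append(_from_recording(
            "correctness", "unlikely_vaccination",
            unlikely_vaccination(extract, cohort)))

    # --- currency: weight timeliness for obesity ----------------------------
    ob_cases = case_sets.get("obesity")
    if ob_cases is None or not vitals_ok or not visits_ok or len(cohort) == 0:
        reason = ("vitals table missing" if not vitals_ok
                  else "visits table missing" if not visits_ok
                  else "empty cohort" if len(cohort) == 0
                  else "obesity definition not evaluable")
        results.append(_not_computable("currency", "weight_timeliness_obesity",
                                       "weight_timeliness_obesity", reason, "obesity"))
    else:
        results.append(_from_timeliness(
            "currency", "weight_timeliness_obesity",
            weight_timeliness_obesity(extract, ob_cases,
                                      window_days=int(windows["vitals_timeliness_days"])),
        ))

    # --- currency: pregnancy follow-up --------------------------------------
    if not extract.has_table("labs") or not visits_ok or len(cohort) == 0:
        reason = ("labs table missing" if not extract.has_table("labs")
                  else "visits table missing" if not visits_ok else "empty cohort")
        results.append(_not_computable("currency", "pregnancy_followup",
                                       "pregnancy_followup", reason))
    else:
        results.append(_from_timeliness(
            "currency", "pregnancy_followup",
            pregnancy_followup(extract, cohort,
                               test_code=cfg["pregnancy_test_code"],
                               window_days=int(windows["pregnancy_followup_days"])),
        ))

    metadata = {
        "emrdq_version": __version__,
        "window_start": extract.window_start.isoformat(),
        "window_end": extract.window_end.isoformat(),
        "dialect": extract.dialect,
        "n_patients": extract.n_patients,
        "cohort_size": len(cohort),
        "exclusions": cohort.exclusions,
        "missing_tables": sorted(extract.missing_tables),
        "standard_population": standard.name,
        "config_hash": _config_hash(cfg),
        "seed": cfg.get("seed"),
    }
    report = DqReport(results=results, metadata=metadata)
    return suppress_small_cells(report, int(cfg["suppression_threshold"]))


def suppress_small_cells(report: DqReport, threshold: int = 5) -> DqReport:
    """Flag results whose numerator is in (0, threshold) for suppression.

    Zero stays rendered (a true 0.0 is informative, not disclosive); the
    flag only controls rendering — exact counts remain in the JSON.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    for r in report.results:
        if r.numerator is not None and 0 < r.numerator < threshold:
            r.suppressed = True
    report.suppression_threshold = threshold
    return report


def _render_rows(report: DqReport) -> list[dict[str, str]]:
    rows = []
    for r in report.results:
        if r.not_computable_reason:
            value = f"not computable ({r.not_computable_reason})"
        elif r.suppressed:
            value = "*"
        elif r.undefined:
            value = "undefined"
        elif r.value_pct is not None:
            value = format_pct(r.value_pct)
            if r.extra.get("standardized_pct") is not None and r.ci95 is not None:
                lo, hi = r.ci95
                value += (f" ({format_pct(r.extra['standardized_pct'])}; "
                          f"{format_pct(lo)}-{format_pct(hi)})")
        elif r.test is not None and "p" in r.test:
            value = f"p = {format_p(r.test['p'])}"
        elif "ages" in r.extra:
            o = r.extra["ages"]["overall"]
            value = f"mean {o['mean']:.1f} (median {o['median']:.1f})"
        else:
            value = ""
        rows.append(
            {
                "domain": r.domain,
                "family": r.family,
                "measure": r.measure_id,
                "condition": r.condition_id or "",
                "value": value,
                "numerator": "*" if r.suppressed else
                             ("" if r.numerator is None else str(r.numerator)),
                "denominator": "" if r.denominator is None else str(r.denominator),
                "reference_pct": "" if r.reference_pct is None else f"{r.reference_pct}",
            }
        )
    return rows


def render(report: DqReport, formats: Sequence[str] = ("json",),
           out_dir: str | Path | None = None) -> dict[str, str]:
    """Render the report; returns {format: text}, optionally writing files."""
    out: dict[str, str] = {}
    for fmt in formats:
        if fmt == "json":
            out["json"] = json.dumps(report.to_dict(), indent=2, sort_keys=True,
                                     default=str)
        elif fmt == "csv":
            rows = _render_rows(report)
            out["csv"] = pd.DataFrame(rows).to_csv(index=False)
        elif fmt == "markdown":
            rows = _render_rows(report)
            lines = ["# EMR data quality report", ""]
            for domain in DOMAINS:
                lines.append(f"## {domain.capitalize()}")
                lines.append("")
                lines.append("| measure | condition | value | n/N |")
                lines.append("|---|---|---|---|")
                for row in rows:
                    if row["domain"] != domain:
                        continue
                    nn = (f"{row['numerator']}/{row['denominator']}"
                          if row["denominator"] else "")
                    lines.append(
                        f"| {row['measure']} | {row['condition']} | {row['value']} | {nn} |"
                    )
                lines.append("")
            out["markdown"] = "\n".join(lines)
        else:
            raise ValueError(f"unknown report format {fmt!r}")
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ext = {"json": "json", "csv": "csv", "markdown": "md"}
        for fmt, text in out.items():
            (out_dir / f"report.{ext[fmt]}").write_text(text)
    return out
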