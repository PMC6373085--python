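"""Synthetic EMR extract generator with a known ground truth.

Generates multi-table extracts whose population structure, condition
prevalence, billing concordance, recording completeness and timeliness are
all configured, so the whole measurement pipeline can be exercised and its
estimates compared with the rates that generated the data.

Two design rules keep every configured rate exactly recoverable:

* every true case emits one "signal" record that its case definition
  detects (a lab result, problem-list term, high blood-pressure pair or
  obese height/weight pair), so case identification is exact while signal
  recording is 1.0;
* signal records are *counted against* the generic recording model — the
  generic emission probability is solved in closed form so that the
  population marginal of "has at least one record" equals the configured
  recording probability, and signal records are placed inside the same
  timely/stale date regions as generic records.

Date regions are laid out so windows cannot collide: condition onsets live
in the first six months, diabetes follow-up BP within a year of onset, and
all other vitals either within a year of the last visit ("timely") or well
before it ("stale").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date
from typing import Mapping

import numpy as np
import pandas as pd

from .comparability import StandardPopulation
from .model import EmrExtract, NO_KNOWN_ALLERGIES, empty_table, validate_extract

__all__ = [
    "SynthConfigError",
    "ConditionConfig",
    "SynthConfig",
    "GroundTruth",
    "generate",
    "degrade",
]

CONDITIONS = (
    "diabetes",
    "hypertension",
    "hypothyroidism",
    "asthma",
    "obesity",
    "urinary_tract_infection",
)

# layout constants (days from window start unless noted)
ONSET_MAX = 182          # condition onsets: first six months
FOLLOWUP_MAX = ONSET_MAX + 365   # diabetes follow-up BP upper edge (547)
STALE_LO = 550           # stale vitals start after every follow-up window
LV_NONRECENT_LO = 950    # earliest last visit; keeps stale region non-empty
MIN_WINDOW_DAYS = LV_NONRECENT_LO + 366 + 90

_ORAL_ANTIHYPERTENSIVES = ("ramipril", "amlodipine")
_BENIGN_PROBLEMS = ("low back pain", "seasonal rhinitis", "gastroesophageal reflux")
_PROBLEM_TERM = {
    "hypothyroidism": "hypothyroidism",
    "asthma": "asthma",
    "urinary_tract_infection": "urinary tract infection",
}
_FREE_TEXT_VARIANTS = {
    "hypothyroidism": ("Hypothyroidism", "hypothyroid", "Low Thyroid."),
    "asthma": ("Asthma", "asthmatic", "ASTHMA"),
    "urinary_tract_infection": ("UTI", "Urinary Tract Infection", "cystitis"),
}
BILLING_CODES = {
    "diabetes": "250",
    "hypertension": "401",
    "hypothyroidism": "244",
    "asthma": "493",
    "obesity": "278",
    "urinary_tract_infection": "599",
}


class SynthConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class ConditionConfig:
    """Per-condition rates for the two-coin-flip billing model."""

    true_prevalence: float
    billing_sensitivity: float
    billing_false_rate: float

    def validate(self, name: str) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name}.{f.name}={v} outside [0, 1]")


def _default_conditions() -> dict[str, ConditionConfig]:
    return {
        # prevalence is defined among the eligible subpopulation:
        # hypertension among adults (18+), asthma among under-18s,
        # the rest among the whole complete-case cohort.
        "diabetes": ConditionConfig(0.12, 0.85, 0.010),
        "hypertension": ConditionConfig(0.28, 0.65, 0.030),
        "hypothyroidism": ConditionConfig(0.07, 0.55, 0.010),
        "asthma": ConditionConfig(0.12, 0.55, 0.010),
        "obesity": ConditionConfig(0.25, 0.30, 0.010),
        "urinary_tract_infection": ConditionConfig(0.05, 0.65, 0.020),
    }


def _default_recording() -> dict[str, float]:
    return {
        "problem_list": 0.70,
        "allergy": 0.48,
        "medication": 0.70,
        "bp": 0.85,
        "height": 0.60,
        "weight": 0.70,
    }


def _default_timeliness() -> dict[str, float]:
    return {"bp": 0.80, "height": 0.45, "weight": 0.60}


@dataclass
class SynthConfig:
    """Generator configuration; the defaults are the study conditions the
    test suite runs under."""

    n_patients: int = 10_000
    seed: int = 0
    window: tuple[str, str] = ("2006-01-01", "2010-12-31")
    age_sex: StandardPopulation | None = None
    conditions: dict[str, ConditionConfig] = field(default_factory=_default_conditions)
    recording: dict[str, float] = field(default_factory=_default_recording)
    timeliness: dict[str, float] = field(default_factory=_default_timeliness)
    signal_recording: float = 1.0      # degradation knob: P(case signal emitted)
    recent_visit_frac: float = 0.80    # patients whose last visit is in the final year
    htn_med_rate: float = 0.70         # hypertension cases given 2 oral anti-hypertensives
    bp_followup_diabetes: float = 0.85 # BP within a year of diabetes onset (among has-BP)
    pregnancy_rate: float = 0.04       # positive test among women 15-45
    pregnancy_followup: float = 0.60   # visit within 62 days of the positive result
    tetanus_misrecord_rate: float = 0.0
    missing_sex_rate: float = 0.002
    missing_age_rate: float = 0.002
    adult_age: int = 18
    dialect: str = "structured"

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise SynthConfigError("n_patients must be positive")
        start, end = pd.Timestamp(self.window[0]), pd.Timestamp(self.window[1])
        if (end - start).days < MIN_WINDOW_DAYS:
            raise SynthConfigError(
                f"window must span at least {MIN_WINDOW_DAYS} days for the "
                f"timeliness layout, got {(end - start).days}"
            )
        for name, cc in self.conditions.items():
            cc.validate(name)
        for group in (self.recording, self.timeliness):
            for k, v in group.items():
                if not 0.0 <= v <= 1.0:
                    raise SynthConfigError(f"rate {k}={v} outside [0, 1]")
        for k in (
            "signal_recording", "recent_visit_frac", "htn_med_rate",
            "bp_followup_diabetes", "pregnancy_rate", "pregnancy_followup",
            "tetanus_misrecord_rate", "missing_sex_rate", "missing_age_rate",
        ):
            v = getattr(self, k)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{k}={v} outside [0, 1]")

    def standard(self) -> StandardPopulation:
        return self.age_sex if self.age_sex is not None else StandardPopulation.synthetic_default()


@dataclass
class GroundTruth:
    """Per-patient latent truth: conditions, onsets and recording flags."""

    table: pd.DataFrame
    config: SynthConfig

    def cases(self, condition: str) -> set[str]:
        t = self.table
        return set(t.loc[t[f"{condition}_case"], "patient_id"])

    def cohort_count(self) -> int:
        return int(self.table["in_cohort"].sum())

    def expected_sensitivity(self, condition: str) -> float:
        return self.config.conditions[condition].billing_sensitivity

    def expected_ppv(self, condition: str) -> float:
        """Analytic PPV of the two-coin-flip billing model, at the realized
        case count: n_case*s / (n_case*s + n_noncase*f)."""
        cc = self.config.conditions[condition]
        t = self.table[self.table["in_cohort"]]
        n_case = int(t[f"{condition}_case"].sum())
        n_non = len(t) - n_case
        denom = n_case * cc.billing_sensitivity + n_non * cc.billing_false_rate
        return float("nan") if denom == 0 else n_case * cc.billing_sensitivity / denom

    def expected_bp_followup_diabetes(self) -> float:
        """Follow-up BP is emitted only for diabetes cases that carry any BP
        record, so the expected measure is f * P(has BP | diabetes case),
        taken at the realized flag frequencies."""
        t = self.table[self.table["in_cohort"] & self.table["diabetes_case"]]
        if t.empty:
            return float("nan")
        return self.config.bp_followup_diabetes * float(t["has_bp"].mean())

    def expected_vitals_timeliness(self, kind: str) -> float:
        """The timeliness measures keep the recording denominators (all
        patients, not just recorded ones), so the expected value is the
        timely fraction among recorded times the recording probability."""
        return self.config.timeliness[kind] * self.config.recording[kind]


def _solve_generic_rate(target: float, forced_frac: float, what: str) -> float:
    """Probability x of a generic record for non-forced patients such that
    forced + (1 - forced) * x equals the target marginal."""
    if forced_frac >= 1.0:
        return 0.0
    x = (target - forced_frac) / (1.0 - forced_frac)
    if x < -1e-9:
        raise SynthConfigError(
            f"{what}: configured rate {target:.3f} below the forced fraction "
            f"{forced_frac:.3f} implied by condition signals"
        )
    return min(max(x, 0.0), 1.0)


def _sample_ages(rng: np.random.Generator, n: int, standard: StandardPopulation):
    wide = standard.wide()
    labels = list(wide.index)
    cells = []
    weights = []
    for bi, band in enumerate(labels):
        for sex in ("male", "female"):
            cells.append((bi, sex))
            weights.append(wide.loc[band, sex])
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    pick = rng.choice(len(cells), size=n, p=w)
    band_idx = np.array([cells[i][0] for i in pick])
    sex = np.array([cells[i][1] for i in pick], dtype=object)
    lo = band_idx * 5
    width = np.where(band_idx == len(labels) - 1, 10, 5)  # 85+ spans ten years
    ages = lo + rng.integers(0, width)
    return ages.astype(int), sex


def _timedelta_days(days: np.ndarray) -> pd.TimedeltaIndex:
    return pd.to_timedelta(np.asarray(days, dtype="int64"), unit="D")


def generate(config: SynthConfig | None = None) -> tuple[EmrExtract, GroundTruth]:
    """Generate a validated extract plus its ground-truth ledger."""
    cfg = config or SynthConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    start = pd.Timestamp(cfg.window[0])
    end = pd.Timestamp(cfg.window[1])
    window_days = (end - start).days

    pid = np.array([f"p{i:06d}" for i in range(n)], dtype=object)
    ages, sex = _sample_ages(rng, n, cfg.standard())
    # birth date consistent with the sampled completed age at window start;
    # the day-level offset can shift the realized completed age by one, so
    # everything downstream uses the realized age, not the sampled one
    offset = rng.integers(0, 365, n)
    birth = start - _timedelta_days(np.round(ages * 365.2425).astype(int) + offset)
    bs = pd.Series(birth)
    before_bday = (bs.dt.month > start.month) | (
        (bs.dt.month == start.month) & (bs.dt.day > start.day)
    )
    idx_age = (start.year - bs.dt.year - before_bday.astype(int)).to_numpy()
    idx_age = np.maximum(idx_age, 0)

    missing_sex = rng.random(n) < cfg.missing_sex_rate
    missing_age = rng.random(n) < cfg.missing_age_rate
    in_cohort = ~missing_sex & ~missing_age
    adult = idx_age >= cfg.adult_age
    minor = idx_age < cfg.adult_age

    # --- visits -----------------------------------------------------------
    recent = rng.random(n) < cfg.recent_visit_frac
    lv_days = np.where(
        recent,
        window_days - rng.integers(0, 366, n),
        rng.integers(LV_NONRECENT_LO, window_days - 365, n),
    )
    lv = start + _timedelta_days(lv_days)

    # --- conditions -------------------------------------------------------
    case: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        p = cfg.conditions[cond].true_prevalence
        eligible = in_cohort.copy()
        if cond == "hypertension":
            eligible &= adult
        elif cond == "asthma":
            eligible &= minor
        case[cond] = eligible & (rng.random(n) < p)
    signal = {cond: case[cond] & (rng.random(n) < cfg.signal_recording) for cond in CONDITIONS}

    onset_days = {cond: rng.integers(0, ONSET_MAX + 1, n) for cond in CONDITIONS}

    # --- timeliness flags -------------------------------------------------
    bp_timely = rng.random(n) < cfg.timeliness["bp"]
    weight_timely = rng.random(n) < cfg.timeliness["weight"]

    # --- recording flags with marginal adjustment -------------------------
    coh = in_cohort
    forced_pl = signal["hypothyroidism"] | signal["asthma"] | signal["urinary_tract_infection"]
    x_pl = _solve_generic_rate(
        cfg.recording["problem_list"], forced_pl[coh].mean() if coh.any() else 0.0, "problem_list"
    )
    generic_pl = ~forced_pl & (rng.random(n) < x_pl)

    has_allergy = rng.random(n) < cfg.recording["allergy"]

    htn_med = signal["hypertension"] & (rng.random(n) < cfg.htn_med_rate)
    recent_coh = coh & recent
    x_med = _solve_generic_rate(
        cfg.recording["medication"],
        htn_med[recent_coh].mean() if recent_coh.any() else 0.0,
        "medication",
    )
    generic_med = ~htn_med & (rng.random(n) < x_med)

    adult_coh = coh & adult
    forced_bp = signal["hypertension"]
    x_bp = _solve_generic_rate(
        cfg.recording["bp"], forced_bp[adult_coh].mean() if adult_coh.any() else 0.0, "bp"
    )
    # minors take the generic rate too; they are outside every BP measure
    # denominator, so only the adult marginal is calibrated
    generic_bp = ~forced_bp & (rng.random(n) < x_bp)
    has_bp = forced_bp | generic_bp

    forced_hw = signal["obesity"]
    x_h = _solve_generic_rate(
        cfg.recording["height"], forced_hw[coh].mean() if coh.any() else 0.0, "height"
    )
    x_w = _solve_generic_rate(
        cfg.recording["weight"], forced_hw[coh].mean() if coh.any() else 0.0, "weight"
    )
    generic_h = ~forced_hw & (rng.random(n) < x_h)
    generic_w = ~forced_hw & (rng.random(n) < x_w)

    # the obesity pair moves with the weight-timeliness flag, so generic
    # heights need a compensated rate for the height marginal to hit target
    n_o = int((forced_hw & coh).sum())
    n_g = int((generic_h & coh).sum())
    t_h, t_w = cfg.timeliness["height"], cfg.timeliness["weight"]
    if n_g > 0:
        t_h_generic = (t_h * (n_o + n_g) - n_o * t_w) / n_g
        t_h_generic = min(max(t_h_generic, 0.0), 1.0)
    else:
        t_h_generic = t_h
    height_timely = rng.random(n) < t_h_generic

    # --- date placement helpers -------------------------------------------
    # timely records fall in [lv-365, lv]; stale records in [STALE_LO, lv-366]
    def timely_days() -> np.ndarray:
        return lv_days - rng.integers(0, 366, n)

    def stale_days() -> np.ndarray:
        span = np.maximum(lv_days - 366 - STALE_LO, 1)
        return STALE_LO + rng.integers(0, span)

    def placed_days(timely: np.ndarray) -> np.ndarray:
        return np.where(timely, timely_days(), stale_days())

    rows: dict[str, list[pd.DataFrame]] = {k: [] for k in (
        "visits", "problems", "medications", "labs", "vitals", "billing",
        "immunizations", "allergies",
    )}

    def add(table: str, mask: np.ndarray, days: np.ndarray, **cols) -> None:
        if not mask.any():
            return
        d = {"patient_id": pid[mask], "event_date": start + _timedelta_days(days[mask])}
        for k, v in cols.items():
            d[k] = v[mask] if isinstance(v, np.ndarray) else v
        rows[table].append(pd.DataFrame(d))

    # --- visits -----------------------------------------------------------
    all_true = np.ones(n, dtype=bool)
    add("visits", all_true, lv_days)
    extra_counts = rng.poisson(3, n)
    max_extra = int(extra_counts.max()) if n else 0

    # pregnancy machinery decides forbidden visit windows before extra visits
    preg_eligible = coh & (sex == "female") & (idx_age >= 15) & (idx_age <= 45)
    preg_pos = preg_eligible & (rng.random(n) < cfg.pregnancy_rate)
    preg_day = rng.integers(1, 366, n)
    preg_followed = preg_pos & (rng.random(n) < cfg.pregnancy_followup)

    for j in range(max_extra):
        has = extra_counts > j
        d = (rng.integers(0, 10_000, n) % np.maximum(lv_days, 1)).astype(int)
        # non-followed positives must have no visit inside (result, result+62]
        forbidden = preg_pos & ~preg_followed & (d > preg_day) & (d <= preg_day + 62)
        add("visits", has & ~forbidden, d)
    add("visits", preg_followed, preg_day + rng.integers(1, 63, n))

    # --- problem list -----------------------------------------------------
    for cond, term in _PROBLEM_TERM.items():
        mask = signal[cond]
        if cfg.dialect == "free_text":
            variants = _FREE_TEXT_VARIANTS[cond]
            pick_v = rng.integers(0, len(variants), n)
            text = np.array([variants[i] for i in pick_v], dtype=object)
        else:
            text = np.full(n, term, dtype=object)
        add("problems", mask, onset_days[cond], text=text, code=None)
    benign_pick = rng.integers(0, len(_BENIGN_PROBLEMS), n)
    benign_text = np.array([_BENIGN_PROBLEMS[i] for i in benign_pick], dtype=object)
    add("problems", generic_pl, rng.integers(0, window_days + 1, n), text=benign_text, code=None)

    # --- allergies --------------------------------------------------------
    marker = rng.random(n) < 0.5
    substance = np.where(marker, NO_KNOWN_ALLERGIES, "penicillin").astype(object)
    add("allergies", has_allergy, rng.integers(0, window_days + 1, n), substance=substance)

    # --- medications ------------------------------------------------------
    # hypertension signal: two high readings on distinct dates inside the
    # patient's timely or stale region; meds are started on the first one
    stale_span = np.maximum(lv_days - 366 - STALE_LO, 2)
    bp1 = np.where(
        bp_timely,
        lv_days - rng.integers(100, 366, n),
        STALE_LO + rng.integers(0, np.maximum(stale_span - 1, 1)),
    )
    region_hi = np.where(bp_timely, lv_days, lv_days - 366)
    bp2 = np.minimum(bp1 + rng.integers(1, 61, n), region_hi)
    bp2 = np.where(bp2 <= bp1, np.minimum(bp1 + 1, region_hi), bp2)
    for drug in _ORAL_ANTIHYPERTENSIVES:
        add("medications", htn_med, bp1, name=drug, class_code=None)
    add("medications", generic_med, rng.integers(0, window_days + 1, n),
        name="acetaminophen", class_code=None)

    # --- vitals: blood pressure ------------------------------------------
    def bp_pair(mask: np.ndarray, days: np.ndarray, sys_lo, sys_hi, dia_lo, dia_hi):
        sysv = rng.uniform(sys_lo, sys_hi, n).round(0)
        diav = rng.uniform(dia_lo, dia_hi, n).round(0)
        add("vitals", mask, days, kind="systolic_bp", value=sysv, units="mmHg")
        add("vitals", mask, days, kind="diastolic_bp", value=diav, units="mmHg")

    bp_pair(forced_bp, bp1, 145, 175, 92, 108)
    bp_pair(forced_bp, bp2, 145, 175, 92, 108)
    generic_bp_days = placed_days(bp_timely)
    bp_pair(generic_bp, generic_bp_days, 100, 135, 62, 85)

    # diabetes follow-up BP: only for cases already carrying a BP record, so
    # neither the recording marginal nor timeliness is disturbed
    dm_followup = case["diabetes"] & has_bp & (rng.random(n) < cfg.bp_followup_diabetes)
    dm_fu_days = onset_days["diabetes"] + rng.integers(0, 366, n)
    bp_pair(dm_followup, dm_fu_days, 100, 135, 62, 85)

    # --- vitals: height and weight ---------------------------------------
    latent_height = rng.uniform(1.50, 1.90, n).round(2)
    pair_days = placed_days(weight_timely)
    obese_bmi = rng.uniform(31.0, 40.0, n)
    obese_weight = (obese_bmi * latent_height**2).round(1)
    add("vitals", forced_hw, pair_days, kind="height", value=latent_height, units="m")
    add("vitals", forced_hw, pair_days, kind="weight", value=obese_weight, units="kg")

    lean_bmi = rng.uniform(19.0, 27.0, n)
    lean_weight = (lean_bmi * latent_height**2).round(1)
    add("vitals", generic_h, placed_days(height_timely), kind="height",
        value=latent_height, units="m")
    add("vitals", generic_w, placed_days(weight_timely), kind="weight",
        value=lean_weight, units="kg")

    # --- labs -------------------------------------------------------------
    hba1c = rng.uniform(6.6, 10.5, n).round(1)
    add("labs", signal["diabetes"], onset_days["diabetes"], test_code="hba1c",
        value=hba1c, units="%", qualitative=None)
    add("labs", preg_pos, preg_day, test_code="pregnancy_hcg",
        value=np.full(n, 1.0), units="qual", qualitative="positive")

    # --- billing ----------------------------------------------------------
    for cond in CONDITIONS:
        cc = cfg.conditions[cond]
        billed_case = case[cond] & (rng.random(n) < cc.billing_sensitivity)
        billed_false = coh & ~case[cond] & (rng.random(n) < cc.billing_false_rate)
        add("billing", billed_case, onset_days[cond], code=BILLING_CODES[cond])
        add("billing", billed_false, rng.integers(0, window_days + 1, n),
            code=BILLING_CODES[cond])
        case[f"_billed_{cond}"] = billed_case | billed_false

    # --- immunizations ----------------------------------------------------
    # legitimate childhood tetanus-conjugate shots for children young enough
    child = coh & (idx_age <= 6)
    shot_day = rng.integers(0, min(window_days, 400) + 1, n)
    add("immunizations", child & (rng.random(n) < 0.5), shot_day, vaccine="DTaP-IPV-Hib")
    # exact completed age at the window end decides misrecord eligibility
    end_before_bday = (bs.dt.month > end.month) | (
        (bs.dt.month == end.month) & (bs.dt.day > end.day)
    )
    age_at_end = (end.year - bs.dt.year - end_before_bday.astype(int)).to_numpy()
    mis_eligible = coh & (age_at_end >= 10)
    mis = mis_eligible & (rng.random(n) < cfg.tetanus_misrecord_rate)
    # placed on the window-end date, where the patient is certainly 10+
    add("immunizations", mis, np.full(n, window_days), vaccine="DTaP-IPV-Hib")

    # --- assemble ---------------------------------------------------------
    tables: dict[str, pd.DataFrame] = {}
    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": pd.array(np.where(missing_sex, None, sex), dtype="string"),
            "birth_date": pd.Series(birth),
        }
    )
    patients.loc[missing_age, "birth_date"] = pd.NaT
    tables["patients"] = patients
    for name, frames in rows.items():
        if frames:
            df = pd.concat(frames, ignore_index=True)
            df = df.sort_values(["patient_id", "event_date"], kind="stable").reset_index(drop=True)
        else:
            df = empty_table(name)
        tables[name] = df

    extract = EmrExtract(
        tables=tables,
        window_start=start.date(),
        window_end=end.date(),
        dialect=cfg.dialect,
    )
    validate_extract(extract)

    ledger = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": np.where(missing_sex, None, sex),
            "index_age": np.where(missing_age, -1, idx_age),
            "in_cohort": in_cohort,
            "recent_visit": recent,
            "last_visit": lv,
            "has_problem": forced_pl | generic_pl,
            "has_allergy": has_allergy,
            "has_medication": htn_med | generic_med,
            "has_bp": has_bp,
            "has_height": forced_hw | generic_h,
            "has_weight": forced_hw | generic_w,
            "bp_timely": bp_timely,
            "weight_timely": weight_timely,
            "dm_followup": dm_followup,
            "preg_positive": preg_pos,
            "preg_followed": preg_followed,
            "tetanus_misrecord": mis,
        }
    )
    for cond in CONDITIONS:
        ledger[f"{cond}_case"] = case[cond]
        ledger[f"{cond}_signal"] = signal[cond]
        ledger[f"{cond}_billed"] = case[f"_billed_{cond}"]
        onset = start + _timedelta_days(onset_days[cond])
        if cond == "hypertension":
            onset = start + _timedelta_days(np.minimum(bp1, bp2))
        elif cond == "obesity":
            onset = start + _timedelta_days(pair_days)
        ledger[f"{cond}_onset"] = pd.Series(onset).where(pd.Series(case[cond]), pd.NaT)
    return extract, GroundTruth(table=ledger, config=cfg)


def degrade(
    extract: EmrExtract,
    knobs: Mapping[str, object],
    seed: int = 0,
) -> EmrExtract:
    """Apply quality-reducing knobs to an extract.

    Supported knobs (each only deletes or back-dates records, so
    completeness and last-visit-anchored currency measures can only fall):

    - ``drop_tables``: list of table names whose rows are all removed
    - ``drop_fraction``: table name → fraction of rows deleted at random
    - ``lag_days``: vitals kind → days by which records are back-dated
    """
    rng = np.random.default_rng(seed)
    known = {"drop_tables", "drop_fraction", "lag_days"}
    unknown = set(knobs) - known
    if unknown:
        raise SynthConfigError(f"unknown degrade knob(s): {sorted(unknown)}")
    tables = {k: v.copy() for k, v in extract.tables.items()}
    log = list(extract.log)

    for name in knobs.get("drop_tables", []) or []:
        if name == "patients":
            raise SynthConfigError("cannot drop the patients table")
        n = len(tables[name])
        tables[name] = empty_table(name)
        log.append(f"degrade: dropped all {n} rows of {name}")

    for name, frac in (knobs.get("drop_fraction", {}) or {}).items():
        if not 0.0 <= float(frac) <= 1.0:
            raise SynthConfigError(f"drop_fraction[{name}]={frac} outside [0, 1]")
        df = tables[name]
        keep = rng.random(len(df)) >= float(frac)
        tables[name] = df[keep].reset_index(drop=True)
        log.append(f"degrade: dropped {int((~keep).sum())} of {len(df)} rows of {name}")

    for kind, days in (knobs.get("lag_days", {}) or {}).items():
        if int(days) < 0:
            raise SynthConfigError("lag_days must be non-negative")
        df = tables["vitals"]
        mask = df["kind"] == kind
        df.loc[mask, "event_date"] = df.loc[mask, "event_date"] - pd.Timedelta(days=int(days))
        log.append(f"degrade: lagged {int(mask.sum())} {kind} rows by {int(days)} days")

    out = dataclasses.replace(extract, tables=tables, log=log)
    validate_extract(out)
    return out
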