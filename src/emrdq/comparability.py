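"""Comparability measures: population structure and standardized prevalence.

Compares the practice population against an external standard population
(age-band x sex counts, e.g. a census) with a goodness-of-fit chi-square and
mean/median ages, and computes crude and directly age(-sex) standardized
prevalence of the test conditions for comparison against published figures.
Published reference prevalences are user-supplied constants echoed in the
report; they are never recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cases import CaseSet
from .model import Cohort, age_band_labels, assign_age_bands

__all__ = [
    "StandardPopulation",
    "ChiSquareResult",
    "PrevalenceResult",
    "age_sex_table",
    "chi_square_vs_standard",
    "mean_median_age",
    "standardized_prevalence",
]

SEXES = ("male", "female")


@dataclass
class StandardPopulation:
    """Age-band x sex reference counts with a name/year tag."""

    table: pd.DataFrame  # columns: age_band, sex, count
    name: str = "standard"
    year: int | None = None

    def __post_init__(self) -> None:
        t = self.table
        required = {"age_band", "sex", "count"}
        if not required <= set(t.columns):
            raise ValueError(f"standard population needs columns {sorted(required)}")
        if (pd.to_numeric(t["count"]) < 0).any():
            raise ValueError("standard population counts must be non-negative")
        if pd.to_numeric(t["count"]).sum() <= 0:
            raise ValueError("standard population must have at least one non-zero cell")

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None, year: int | None = None):
        df = pd.read_csv(path)
        return cls(table=df, name=name or Path(path).stem, year=year)

    @classmethod
    def synthetic_default(cls) -> "StandardPopulation":
        """Shipped synthetic age-sex pyramid (a census stand-in for testing)."""
        path = resources.files("emrdq.data").joinpath("synthetic_standard_population.csv")
        return cls(table=pd.read_csv(str(path)), name="synthetic_standard", year=None)

    def wide(self, band_width: int = 5, top_band_start: int = 85) -> pd.DataFrame:
        """Band x sex count matrix aligned to the model's band labels."""
        labels = age_band_labels(band_width, top_band_start)
        out = (
            self.table.pivot_table(index="age_band", columns="sex", values="count", aggfunc="sum")
            .reindex(labels)
            .fillna(0.0)
        )
        for s in SEXES:
            if s not in out.columns:
                out[s] = 0.0
        return out[list(SEXES)].astype(float)

    def weights(self, sex_specific: bool = True, band_width: int = 5, top_band_start: int = 85) -> pd.Series:
        """Stratum share of the standard population (sums to 1)."""
        wide = self.wide(band_width, top_band_start)
        if sex_specific:
            stacked = wide.stack()
            return stacked / stacked.sum()
        by_band = wide.sum(axis=1)
        return by_band / by_band.sum()


def age_sex_table(cohort: Cohort, band_width: int = 5, top_band_start: int = 85) -> pd.DataFrame:
    """Counts of cohort members by age band (rows) and sex (columns)."""
    if len(cohort) == 0:
        raise ValueError("age_sex_table needs a non-empty cohort")
    members = cohort.members
    bands = assign_age_bands(members["index_age"].to_numpy(), band_width, top_band_start)
    table = pd.crosstab(bands, members["sex"].astype(str), dropna=False)
    table = table.reindex(age_band_labels(band_width, top_band_start)).fillna(0)
    for s in SEXES:
        if s not in table.columns:
            table[s] = 0
    return table[list(SEXES)].astype(int)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    pooled_cells: list[str] = field(default_factory=list)


def _pool_column(observed: np.ndarray, expected: np.ndarray, labels: list[str], threshold: float):
    """Pool adjacent age bands (within one sex) so every expected count
    reaches the validity threshold; returns pooled (obs, exp, label) lists."""
    obs_groups: list[float] = []
    exp_groups: list[float] = []
    lab_groups: list[list[str]] = []
    cur_o = cur_e = 0.0
    cur_l: list[str] = []
    for o, e, l in zip(observed, expected, labels):
        cur_o += o
        cur_e += e
        cur_l.append(l)
        if cur_e >= threshold:
            obs_groups.append(cur_o)
            exp_groups.append(cur_e)
            lab_groups.append(cur_l)
            cur_o = cur_e = 0.0
            cur_l = []
    if cur_l:
        if exp_groups:
            obs_groups[-1] += cur_o
            exp_groups[-1] += cur_e
            lab_groups[-1].extend(cur_l)
        elif cur_e > 0:
            obs_groups.append(cur_o)
            exp_groups.append(cur_e)
            lab_groups.append(cur_l)
    return obs_groups, exp_groups, lab_groups


def chi_square_vs_standard(
    observed: pd.DataFrame,
    standard: StandardPopulation,
    pool_threshold: float = 5.0,
) -> ChiSquareResult:
    """Goodness-of-fit chi-square of the observed band x sex counts against
    the standard population's proportions.

    Expected counts are standard-population shares times the observed total,
    so the statistic is invariant to the absolute scale of the standard.
    Cells with expected counts below ``pool_threshold`` are pooled into the
    adjacent age band within the same sex (logged in ``pooled_cells``);
    df = (#cells after pooling) - 1.
    """
    std_wide = standard.wide().reindex(observed.index).fillna(0.0)
    total_std = std_wide.to_numpy().sum()
    if total_std <= 0:
        raise ValueError("standard population is all zero over the observed bands")
    n = observed.to_numpy().sum()
    expected = std_wide / total_std * n

    obs_all: list[float] = []
    exp_all: list[float] = []
    pooled: list[str] = []
    labels = list(observed.index.astype(str))
    for sex in observed.columns:
        o, e, groups = _pool_column(
            observed[sex].to_numpy(float), expected[sex].to_numpy(float), labels, pool_threshold
        )
        obs_all.extend(o)
        exp_all.extend(e)
        pooled.extend(f"{sex}:{'+'.join(g)}" for g in groups if len(g) > 1)
    obs_arr = np.asarray(obs_all)
    exp_arr = np.asarray(exp_all)
    keep = exp_arr > 0
    stat = float(((obs_arr[keep] - exp_arr[keep]) ** 2 / exp_arr[keep]).sum())
    df = int(keep.sum()) - 1
    p = float(stats.chi2.sf(stat, df)) if df > 0 else float("nan")
    return ChiSquareResult(statistic=stat, df=df, p=p, pooled_cells=pooled)


def mean_median_age(cohort: Cohort) -> dict[str, dict[str, float]]:
    """Mean and median index age, overall and per sex."""
    if len(cohort) == 0:
        raise ValueError("mean_median_age needs a non-empty cohort")
    out: dict[str, dict[str, float]] = {}
    members = cohort.members
    groups = {"overall": members}
    for s in SEXES:
        groups[s] = members[members["sex"] == s]
    for name, g in groups.items():
        if g.empty:
            out[name] = {"mean": float("nan"), "median": float("nan"), "n": 0}
        else:
            ages = g["index_age"].astype(float)
            out[name] = {
                "mean": float(ages.mean()),
                "median": float(ages.median()),
                "n": int(len(g)),
            }
    return out


@dataclass
class PrevalenceResult:
    condition_id: str
    crude_pct: float
    standardized_pct: float | None
    ci95: tuple[float, float] | None
    n_cases: int
    n_cohort: int
    reference_pct: float | None = None
    dropped_strata: list[str] = field(default_factory=list)
    ci_method: str = "gamma"


def _gamma_ci(y: float, v: float, wm: float, alpha: float) -> tuple[float, float]:
    """Fay-Feuer gamma interval for a directly standardized rate.

    ``y`` is the standardized rate (per 1), ``v`` its variance estimate and
    ``wm`` the largest single-case weight contribution max_s(w_s / n_s).
    """
    if y <= 0 or v <= 0:
        lower = 0.0
    else:
        lower = float(stats.gamma.ppf(alpha / 2, a=y * y / v, scale=v / y))
    yu = y + wm
    vu = v + wm * wm
    if yu <= 0 or vu <= 0:
        upper = 0.0
    else:
        upper = float(stats.gamma.ppf(1 - alpha / 2, a=yu * yu / vu, scale=vu / yu))
    return lower, upper


def standardized_prevalence(
    cases: CaseSet,
    cohort: Cohort,
    standard: StandardPopulation,
    sex_specific: bool = True,
    alpha: float = 0.05,
    band_width: int = 5,
    top_band_start: int = 85,
    reference_pct: float | None = None,
) -> PrevalenceResult:
    """Crude and directly standardized prevalence (percent) with a 95% CI.

    Strata are 5-year band x sex by default (band-only with
    ``sex_specific=False``). Strata with zero cohort members are dropped and
    the standard weights renormalized over the remainder (logged in
    ``dropped_strata``). The CI is the gamma (Fay-Feuer) interval for a
    directly standardized rate.
    """
    if len(cohort) == 0:
        raise ValueError("standardized_prevalence needs a non-empty cohort")
    members = cohort.members
    case_ids = cases.case_ids
    bands = assign_age_bands(members["index_age"].to_numpy(), band_width, top_band_start)
    df = pd.DataFrame(
        {
            "band": bands.astype(str),
            "sex": members["sex"].astype(str),
            "case": members["patient_id"].isin(case_ids).to_numpy(),
        }
    )
    crude = 100.0 * df["case"].sum() / len(df)

    keys = ["band", "sex"] if sex_specific else ["band"]
    grouped = df.groupby(keys, observed=False).agg(n=("case", "size"), x=("case", "sum"))
    weights = standard.weights(sex_specific=sex_specific, band_width=band_width,
                               top_band_start=top_band_start)
    if not sex_specific:
        grouped.index = grouped.index.astype(str)
    aligned = grouped.reindex(weights.index).fillna({"n": 0, "x": 0})

    nonzero = aligned["n"] > 0
    dropped = [
        ":".join(map(str, i)) if isinstance(i, tuple) else str(i)
        for i, w in weights[~nonzero].items()
        if w > 0
    ]
    w = weights[nonzero]
    w = w / w.sum() if w.sum() > 0 else w
    n_s = aligned.loc[nonzero, "n"].astype(float)
    x_s = aligned.loc[nonzero, "x"].astype(float)
    r_s = x_s / n_s
    y = float((w * r_s).sum())
    v = float((w * w / (n_s * n_s) * x_s).sum())  # Poisson-style Fay-Feuer variance
    wm = float((w / n_s).max()) if len(w) else 0.0
    lo, hi = _gamma_ci(y, v, wm, alpha)
    return PrevalenceResult(
        condition_id=cases.condition_id,
        crude_pct=float(crude),
        standardized_pct=100.0 * y,
        ci95=(100.0 * lo, 100.0 * hi),
        n_cases=int(df["case"].sum()),
        n_cohort=len(df),
        reference_pct=reference_pct,
        dropped_strata=dropped,
        ci_method="gamma",
    )
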