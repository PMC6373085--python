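"""Population-structure comparison and standardized prevalence."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emrdq.cases import CaseSet
from emrdq.comparability import (
    StandardPopulation,
    age_sex_table,
    chi_square_vs_standard,
    mean_median_age,
    standardized_prevalence,
)
from emrdq.model import Cohort, complete_case_cohort

from conftest import make_extract, patient


def cohort_from(rows):
    """rows: (pid, sex, age)."""
    return Cohort(
        members=pd.DataFrame(
            {"patient_id": [r[0] for r in rows],
             "sex": [r[1] for r in rows],
             "index_age": [r[2] for r in rows]}
        ),
        index_date=pd.Timestamp("2006-01-01").date(),
        exclusions={},
    )


def uniform_standard(cells):
    """cells: (band, sex, count)."""
    return StandardPopulation(
        table=pd.DataFrame(cells, columns=["age_band", "sex", "count"]),
        name="test",
    )


class TestAgeSexTable:
    def test_counting(self):
        coh = cohort_from([("a", "male", 3), ("b", "male", 3), ("c", "female", 87)])
        t = age_sex_table(coh)
        assert t.loc["0-4", "male"] == 2
        assert t.loc["85+", "female"] == 1
        assert t.to_numpy().sum() == 3

    def test_sum_preserved_under_band_width(self):
        coh = cohort_from([(f"p{i}", "female", i) for i in range(60)])
        for width in (5, 10, 15):
            t = age_sex_table(coh, band_width=width, top_band_start=width * 4)
            assert t.to_numpy().sum() == 60

    def test_matches_brute_force_group_by(self, synth_small):
        ex, _ = synth_small
        coh = complete_case_cohort(ex)
        table = age_sex_table(coh)
        # independent: plain dict counting
        from emrdq.model import age_band

        counts: dict[tuple[str, str], int] = {}
        for _, row in coh.members.iterrows():
            key = (age_band(int(row["index_age"])), str(row["sex"]))
            counts[key] = counts.get(key, 0) + 1
        for (band, sex), n in counts.items():
            assert table.loc[band, sex] == n
        assert table.to_numpy().sum() == len(coh)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            age_sex_table(cohort_from([]))


class TestChiSquare:
    def test_perfect_fit_gives_zero(self):
        coh = cohort_from(
            [(f"m{i}", "male", 10) for i in range(50)]
            + [(f"f{i}", "female", 10) for i in range(50)]
        )
        std = uniform_standard([("10-14", "male", 500), ("10-14", "female", 500)])
        res = chi_square_vs_standard(age_sex_table(coh), std)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_two_cells(self):
        """observed (60, 40) against a 50/50 standard: sum (O-E)^2/E = 4."""
        coh = cohort_from(
            [(f"m{i}", "male", 10) for i in range(60)]
            + [(f"f{i}", "female", 10) for i in range(40)]
        )
        std = uniform_standard([("10-14", "male", 500), ("10-14", "female", 500)])
        res = chi_square_vs_standard(age_sex_table(coh), std)
        assert res.statistic == pytest.approx(4.0)
        assert res.df == 1
        assert res.p == pytest.approx(stats.chi2.sf(4.0, 1))
        assert res.p == pytest.approx(0.0455, abs=5e-4)

    def test_invariant_to_standard_scale(self):
        coh = cohort_from(
            [(f"m{i}", "male", 12) for i in range(30)]
            + [(f"f{i}", "female", 33) for i in range(70)]
        )
        small = uniform_standard(
            [("10-14", "male", 40), ("30-34", "female", 60)])
        big = uniform_standard(
            [("10-14", "male", 40_000), ("30-34", "female", 60_000)])
        a = chi_square_vs_standard(age_sex_table(coh), small)
        b = chi_square_vs_standard(age_sex_table(coh), big)
        assert a.statistic == pytest.approx(b.statistic)

    def test_matches_textbook_computation_on_fixture(self, synth_small):
        ex, _ = synth_small
        coh = complete_case_cohort(ex)
        obs = age_sex_table(coh)
        std = StandardPopulation.synthetic_default()
        res = chi_square_vs_standard(obs, std, pool_threshold=0.0)
        exp = std.wide().reindex(obs.index).to_numpy()
        exp = exp / exp.sum() * obs.to_numpy().sum()
        o, e = obs.to_numpy().ravel(), exp.ravel()
        keep = e > 0
        stat = ((o[keep] - e[keep]) ** 2 / e[keep]).sum()
        assert res.statistic == pytest.approx(stat, rel=1e-12)

    def test_small_expected_cells_are_pooled(self):
        coh = cohort_from(
            [(f"a{i}", "male", 2) for i in range(99)] + [("b", "male", 7)]
        )
        std = uniform_standard(
            [("0-4", "male", 90), ("5-9", "male", 5), ("10-14", "male", 5)])
        res = chi_square_vs_standard(age_sex_table(coh), std, pool_threshold=6.0)
        assert res.pooled_cells  # the 5% cells were merged into one
        assert res.df == 1
        # pooled cells: observed (99, 1) vs expected (90, 10)
        assert res.statistic == pytest.approx(81 / 90 + 81 / 10)


class TestMeanMedianAge:
    def test_singleton_and_midpoint(self):
        one = mean_median_age(cohort_from([("a", "male", 38)]))
        assert one["overall"] == {"mean": 38.0, "median": 38.0, "n": 1}
        two = mean_median_age(cohort_from([("a", "male", 30), ("b", "male", 40)]))
        assert two["overall"]["mean"] == 35.0
        assert two["overall"]["median"] == 35.0

    def test_matches_numpy_on_fixture(self, synth_small):
        ex, _ = synth_small
        coh = complete_case_cohort(ex)
        res = mean_median_age(coh)
        ages = np.sort(coh.members["index_age"].to_numpy(float))
        assert res["overall"]["mean"] == pytest.approx(ages.mean())
        assert res["overall"]["median"] == pytest.approx(np.median(ages))


def case_set(cond, case_ids, onset="2007-01-01"):
    ids = sorted(case_ids)
    return CaseSet(
        cond,
        pd.DataFrame(
            {"patient_id": ids, "is_case": [True] * len(ids),
             "onset_date": pd.Timestamp(onset)}
        ),
    )


class TestStandardizedPrevalence:
    def test_homogeneous_rates_reproduce_common_rate(self):
        rows = (
            [(f"y{i}", "male", 10) for i in range(100)]
            + [(f"o{i}", "male", 50) for i in range(100)]
        )
        coh = cohort_from(rows)
        cases = case_set("diabetes", [f"y{i}" for i in range(10)]
                         + [f"o{i}" for i in range(10)])
        std = uniform_standard([("10-14", "male", 1), ("50-54", "male", 99)])
        res = standardized_prevalence(cases, coh, std)
        assert res.crude_pct == pytest.approx(10.0)
        assert res.standardized_pct == pytest.approx(10.0, abs=1e-12)

    def test_weighted_sum_closed_form(self):
        """rates 10% and 20% at weights 0.3/0.7 -> 17.0%."""
        rows = (
            [(f"y{i}", "male", 10) for i in range(100)]
            + [(f"o{i}", "male", 50) for i in range(100)]
        )
        coh = cohort_from(rows)
        cases = case_set("x", [f"y{i}" for i in range(10)]
                         + [f"o{i}" for i in range(20)])
        std = uniform_standard([("10-14", "male", 30), ("50-54", "male", 70)])
        res = standardized_prevalence(cases, coh, std)
        assert res.standardized_pct == pytest.approx(17.0, abs=1e-12)
        lo, hi = res.ci95
        assert lo <= res.standardized_pct <= hi

    def test_zero_cases(self):
        coh = cohort_from([(f"p{i}", "female", 30) for i in range(50)])
        cases = case_set("x", [])
        std = uniform_standard([("30-34", "female", 1)])
        res = standardized_prevalence(cases, coh, std)
        assert res.crude_pct == 0.0
        assert res.standardized_pct == 0.0
        assert res.ci95[0] == 0.0

    def test_bounded_by_stratum_rates(self, synth_small, definitions):
        from emrdq.cases import identify_cases
        from emrdq.model import assign_age_bands

        ex, _ = synth_small
        coh = complete_case_cohort(ex)
        cases = identify_cases(ex, definitions["hypothyroidism"], coh)
        std = StandardPopulation.synthetic_default()
        res = standardized_prevalence(cases, coh, std)
        m = coh.members.copy()
        m["band"] = assign_age_bands(m["index_age"].to_numpy()).astype(str)
        m["case"] = m["patient_id"].isin(cases.case_ids)
        rates = m.groupby(["band", "sex"], observed=True)["case"].mean() * 100
        assert rates.min() - 1e-9 <= res.standardized_pct <= rates.max() + 1e-9

    def test_crude_equals_standardized_when_structure_matches(self):
        """If the standard has the cohort's own structure, weighting by it
        recovers the crude rate exactly."""
        rows = (
            [(f"y{i}", "male", 10) for i in range(40)]
            + [(f"o{i}", "female", 50) for i in range(60)]
        )
        coh = cohort_from(rows)
        cases = case_set("x", [f"y{i}" for i in range(5)]
                         + [f"o{i}" for i in range(30)])
        std = uniform_standard([("10-14", "male", 40), ("50-54", "female", 60)])
        res = standardized_prevalence(cases, coh, std)
        assert res.standardized_pct == pytest.approx(res.crude_pct, abs=1e-12)

    def test_empty_strata_dropped_and_logged(self):
        coh = cohort_from([(f"p{i}", "male", 10) for i in range(100)])
        cases = case_set("x", [f"p{i}" for i in range(10)])
        std = uniform_standard([("10-14", "male", 50), ("50-54", "male", 50)])
        res = standardized_prevalence(cases, coh, std)
        assert res.dropped_strata == ["50-54:male"]
        assert res.standardized_pct == pytest.approx(10.0)
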