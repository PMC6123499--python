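"""Reporting layer: tabulation, Sullivan expectancies, traces, ranges."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import caresim as cs
from caresim.engine import RunResult
from caresim.exceptions import InputDomainError, ReportingError
from caresim.outputs import (
    combined_dependency,
    prevalence_from_snapshot,
    range_over_runs,
    round_half_away,
    tabulate,
)
from caresim.population import DISEASES


def _snapshot(rows):
    """Build a minimal snapshot frame from (sex, age, phys_dep, cognition,
    n_diseases, dementia, alive) tuples."""
    data = []
    for i, (sex, age, dep, cog, ndis, dem, alive) in enumerate(rows):
        rec = {
            "id": i, "study": "toy", "sex": sex, "age_months": age * 12,
            "education": 1, "occupation": 1, "smoking": 0, "bmi_class": 0,
            "physical_activity": 1,
            **{d: 0 for d in DISEASES},
            "vision": 0, "hearing": 0, "mmse": 30 if cog == 0 else 5,
            "cognition": cog, "phys_dep": dep, "residence": 0,
            "dementia": dem, "alive": alive, "weight": 1.0,
        }
        for d in DISEASES[:ndis]:
            rec[d] = 1
        data.append(rec)
    return pd.DataFrame(data)


class TestTabulate:
    def test_hand_tally_ten_person_snapshot(self):
        rows = [
            # sex, age, dep, cog, ndis, dementia, alive
            (0, 70, 0, 0, 0, 0, 1),
            (0, 70, 0, 0, 0, 0, 1),
            (0, 72, 1, 0, 2, 0, 1),
            (1, 78, 2, 0, 3, 1, 1),
            (1, 80, 0, 3, 1, 1, 1),   # severe cognition -> high dependency
            (1, 86, 3, 0, 4, 1, 1),
            (0, 88, 1, 2, 2, 0, 1),
            (1, 66, 0, 0, 0, 0, 0),   # dead: excluded
            (0, 55, 3, 0, 5, 0, 1),   # under 65: excluded
            (1, 91, 2, 0, 1, 0, 1),
        ]
        res = RunResult(run_index=0, master_seed=0, snapshots={2015: _snapshot(rows)})
        cube = tabulate([res])
        counts = cube.margin(["age_band", "dependency"]).set_index(["age_band", "dependency"])["count"]
        assert counts[("65-74", 0)] == 2
        assert counts[("65-74", 1)] == 1
        assert counts[("75-84", 2)] == 1
        assert counts[("75-84", 3)] == 1       # the severe-cognition floor
        assert counts[("85+", 3)] == 1
        assert counts[("85+", 1)] == 1
        assert counts[("85+", 2)] == 1
        assert counts.sum() == 8               # dead + under-65 excluded

    def test_margins_additive(self, params_small):
        snap = _snapshot([(s, 65 + i % 30, i % 4, 0, i % 3, i % 2, 1)
                          for i, s in enumerate([0, 1] * 40)])
        res = RunResult(run_index=0, master_seed=0, snapshots={2015: snap})
        cube = tabulate([res])
        total = cube.margin(["year"])["count"].sum()
        by_dep = cube.margin(["dependency"])["count"].sum()
        by_all = cube.counts["count"].sum()
        assert total == by_dep == by_all == 80

    def test_empty_population_gives_empty_cube(self):
        snap = _snapshot([(0, 70, 0, 0, 0, 0, 0)])  # everyone dead
        res = RunResult(run_index=0, master_seed=0, snapshots={2015: snap})
        cube = tabulate([res])
        assert cube.counts["count"].sum() == 0

    def test_missing_snapshots_rejected(self):
        with pytest.raises(ReportingError):
            tabulate([RunResult(run_index=0, master_seed=0)])

    def test_scale_factor_applied(self):
        snap = _snapshot([(0, 70, 0, 0, 0, 0, 1)] * 5)
        res = RunResult(run_index=0, master_seed=0, snapshots={2015: snap})
        cube = tabulate([res], scale_factor=100.0)
        scaled = cube.population_counts(["year"])
        assert scaled["count"].iloc[0] == 500.0


class TestArithmetic:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(3655, 5602, 53.3), (1591, 2778, 74.6), (3655, 4493, 22.9),
         (1591, 2535, 59.3), (5541, 7388, 33.3), (783, 1065, 36.0),
         (417, 123, -70.5), (100, 100, 0.0)],
    )
    def test_relative_change(self, start, end, expected):
        assert cs.relative_change(start, end) == expected

    def test_relative_change_zero_start_undefined(self):
        with pytest.raises(InputDomainError):
            cs.relative_change(0, 10)

    @pytest.mark.parametrize(
        "years,total,expected",
        [(1.2, 18.7, 6.4), (2.0, 21.1, 9.5), (1.4, 18.7, 7.5),
         (5.1, 22.2, 23.0), (0.0, 15.0, 0.0)],
    )
    def test_proportion_of_le(self, years, total, expected):
        assert cs.proportion_of_le(years, total) == expected

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(0.25, 1) == 0.3
        assert round_half_away(-0.25, 1) == -0.3
        assert round_half_away(2.349, 1) == 2.3


def _toy_lifetable(survivals):
    ages = np.arange(65, 65 + len(survivals))
    rows = [pd.DataFrame({"sex": s, "age": ages, "survival": survivals}) for s in ("male", "female")]
    return cs.LifeTable(pd.concat(rows, ignore_index=True))


def _uniform_prevalence(ages, proportions):
    rows = []
    for age in ages:
        for level, p in enumerate(proportions):
            rows.append({"age": age, "dependency": level, "proportion": p})
    return pd.DataFrame(rows)


class TestSullivan:
    def test_three_age_hand_computed_oracle(self):
        # l = [1e5, 5e4, 2.5e4]; L = [75e3, 37.5e3, 2.5e4/ln2]
        lt = _toy_lifetable([0.5, 0.5, 0.5])
        prev = pd.DataFrame(
            [
                {"age": 65, "dependency": 0, "proportion": 0.8},
                {"age": 65, "dependency": 2, "proportion": 0.2},
                {"age": 66, "dependency": 0, "proportion": 0.5},
                {"age": 66, "dependency": 3, "proportion": 0.5},
                {"age": 67, "dependency": 1, "proportion": 1.0},
            ]
        )
        row = cs.sullivan(prev, lt, "male", from_age=65)
        L = [75_000.0, 37_500.0, 25_000.0 / np.log(2)]
        l65 = 1e5
        assert row.total_le == pytest.approx(sum(L) / l65, rel=1e-12)
        assert row.years_by_level[0] == pytest.approx((0.8 * L[0] + 0.5 * L[1]) / l65, rel=1e-12)
        assert row.years_by_level[1] == pytest.approx(L[2] / l65, rel=1e-12)
        assert row.years_by_level[2] == pytest.approx(0.2 * L[0] / l65, rel=1e-12)
        assert row.years_by_level[3] == pytest.approx(0.5 * L[1] / l65, rel=1e-12)

    def test_constant_prevalence_factorises(self, lifetable):
        ages = np.arange(65, lifetable.age_max + 1)
        prev = _uniform_prevalence(ages, [0.55, 0.25, 0.12, 0.08])
        row = cs.sullivan(prev, lifetable, "female", from_age=65)
        total = lifetable.life_expectancy("female", 65)
        assert row.total_le == pytest.approx(total, rel=1e-12)
        assert row.years_by_level[1] == pytest.approx(0.25 * total, rel=1e-9)

    def test_all_independent_population(self, lifetable):
        ages = np.arange(65, lifetable.age_max + 1)
        prev = _uniform_prevalence(ages, [1.0, 0.0, 0.0, 0.0])
        row = cs.sullivan(prev, lifetable, "male")
        assert row.years_by_level[0] == pytest.approx(row.total_le, rel=1e-12)
        assert row.years_by_level[3] == 0.0

    def test_invalid_prevalence_sum_rejected(self, lifetable):
        ages = np.arange(65, lifetable.age_max + 1)
        prev = _uniform_prevalence(ages, [0.5, 0.2, 0.1, 0.1])  # sums to 0.9
        with pytest.raises(InputDomainError, match="sum to 1"):
            cs.sullivan(prev, lifetable, "male")

    def test_missing_age_rejected(self, lifetable):
        prev = _uniform_prevalence(np.arange(65, 80), [0.7, 0.2, 0.06, 0.04])
        with pytest.raises(InputDomainError, match="missing"):
            cs.sullivan(prev, lifetable, "male")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_state_years_always_sum_to_total(self, data):
        # conservation: sum of state expectancies equals total LE to 1e-9
        n_ages = data.draw(st.integers(2, 12))
        survivals = data.draw(
            st.lists(st.floats(0.05, 1.0, allow_nan=False), min_size=n_ages, max_size=n_ages)
        )
        lt = _toy_lifetable(survivals)
        rows = []
        for age in range(65, 65 + n_ages):
            raw = data.draw(
                st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=4, max_size=4)
                .filter(lambda v: sum(v) > 1e-6)
            )
            total = sum(raw)
            for level in range(4):
                rows.append({"age": age, "dependency": level, "proportion": raw[level] / total})
        row = cs.sullivan(pd.DataFrame(rows), lt, "male")
        assert sum(row.years_by_level.values()) == pytest.approx(row.total_le, abs=1e-9)

    def test_lower_survival_lowers_total_le(self):
        good = _toy_lifetable([0.95] * 20)
        bad = _toy_lifetable([0.85] * 20)
        ages = np.arange(65, 85)
        prev = _uniform_prevalence(ages, [1.0, 0.0, 0.0, 0.0])
        assert (
            cs.sullivan(prev, bad, "male").total_le < cs.sullivan(prev, good, "male").total_le
        )


class TestPrevalenceFromSnapshot:
    def test_covers_requested_ages_and_sums_to_one(self, base_small):
        prev = prevalence_from_snapshot(base_small, sex_code=1, age_min=65, age_max=105)
        sums = prev.groupby("age")["proportion"].sum()
        assert set(sums.index) == set(range(65, 106))
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-12)

    def test_empty_range_rejected(self, base_small):
        nobody = base_small[base_small["alive"] == 0]
        with pytest.raises(ReportingError):
            prevalence_from_snapshot(nobody, sex_code=0, age_min=65, age_max=80)


class TestCohortTrace:
    def test_flat_for_immortal_transition_free_population(self):
        snap = _snapshot([(0, 70, 0, 0, 0, 0, 1)] * 30 + [(0, 76, 1, 0, 0, 0, 1)] * 10)
        older = snap.copy()
        older["age_months"] = older["age_months"] + 60
        res = RunResult(run_index=0, master_seed=0, snapshots={2015: snap, 2020: older})
        trace = cs.cohort_trace([res])
        by_cohort = trace.pivot_table(index=["sex", "cohort"], columns="year",
                                      values="proportion_independent")
        complete = by_cohort.dropna()
        assert np.allclose(complete[2015], complete[2020])

    def test_scripted_transitions_reproduced(self):
        snap15 = _snapshot([(1, 70, 0, 0, 0, 0, 1)] * 8 + [(1, 70, 1, 0, 0, 0, 1)] * 2)
        snap20 = _snapshot([(1, 75, 0, 0, 0, 0, 1)] * 5 + [(1, 75, 1, 0, 0, 0, 1)] * 5)
        res = RunResult(run_index=0, master_seed=0, snapshots={2015: snap15, 2020: snap20})
        trace = cs.cohort_trace([res])
        t = trace.set_index(["year", "cohort"])["proportion_independent"]
        assert t[(2015, "1941-1945")] == pytest.approx(0.8)
        assert t[(2020, "1941-1945")] == pytest.approx(0.5)

    def test_under_65_cohorts_suppressed_until_old_enough(self):
        snap = _snapshot([(0, 62, 0, 0, 0, 0, 1)] * 5)  # born 1953
        later = snap.copy()
        later["age_months"] += 10 * 12
        res = RunResult(run_index=0, master_seed=0, snapshots={2015: snap, 2025: later})
        trace = cs.cohort_trace([res])
        cohort_years = trace[trace.cohort == "1951-1955"]["year"].values
        assert 2015 not in cohort_years  # youngest member only 60 in 2015
        assert 2025 in cohort_years      # whole cohort 70-74 by 2025

    def test_needs_two_snapshot_years(self):
        res = RunResult(run_index=0, master_seed=0, snapshots={2015: _snapshot([(0, 70, 0, 0, 0, 0, 1)])})
        with pytest.raises(ReportingError):
            cs.cohort_trace([res])


class TestRangeOverRuns:
    def test_single_run_collapses(self):
        assert range_over_runs([4.2]) == (4.2, 4.2, 4.2)

    def test_headline_within_range(self):
        head, lo, hi = range_over_runs([3.0, 5.0, 1.0])
        assert lo <= head <= hi
        assert (lo, hi) == (1.0, 5.0)

    def test_permutation_changes_only_headline(self):
        _, lo1, hi1 = range_over_runs([3.0, 5.0, 1.0])
        _, lo2, hi2 = range_over_runs([5.0, 1.0, 3.0])
        assert (lo1, hi1) == (lo2, hi2)

    def test_empty_rejected(self):
        with pytest.raises(ReportingError):
            range_over_runs([])
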