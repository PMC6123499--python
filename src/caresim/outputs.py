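"""Reporting: counts, prevalence, multimorbidity cross-tabs, Sullivan
health expectancies and ten-run ranges.

The reporting surfaces mirror the standard presentation of dependency
projections: absolute numbers and prevalence by sex and age band (65-74,
75-84, >=85, all 65+) at each output year, relative changes between years,
cross-tabulations of substantial dependency with dementia and disease-count
strata (0-1, 2, >=3), birth-cohort independence traces, and period life
expectancy at 65 partitioned into years lived at each dependency level by
Sullivan's method.  Headline values come from the first run; uncertainty is
shown as the (min, max) range over repeated runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunResult
from .exceptions import InputDomainError, ReportingError
from .interval_of_need import IntervalOfNeed
from .lifetable import LifeTable
from .population import DISEASES

__all__ = [
    "OutputCube",
    "HealthExpectancyRow",
    "combined_dependency",
    "tabulate",
    "relative_change",
    "proportion_of_le",
    "sullivan",
    "prevalence_from_snapshot",
    "cohort_trace",
    "range_over_runs",
    "round_half_away",
]

AGE_BANDS_REPORT = (("65-74", 65, 74), ("75-84", 75, 84), ("85+", 85, 1000))
DISEASE_STRATA = ("0-1", "2", "3+")


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def combined_dependency(snapshot: pd.DataFrame) -> np.ndarray:
    """Interval of need: physical dependency floored at high by severe cognition."""
    phys = snapshot["phys_dep"].to_numpy()
    severe = snapshot["cognition"].to_numpy() == 3
    return np.maximum(phys, np.where(severe, IntervalOfNeed.HIGH, IntervalOfNeed.INDEPENDENT)).astype(np.int8)


def _age_band(age_years: np.ndarray) -> np.ndarray:
    labels = np.full(age_years.shape, "", dtype=object)
    for name, lo, hi in AGE_BANDS_REPORT:
        labels[(age_years >= lo) & (age_years <= hi)] = name
    return labels


def _disease_stratum(n_dis: np.ndarray) -> np.ndarray:
    return np.select([n_dis <= 1, n_dis == 2], ["0-1", "2"], default="3+").astype(object)


@dataclass
class OutputCube:
    """Tidy counts by run x year x sex x age band x dependency x stratum x dementia.

    ``scale_factor`` converts simulated individuals to population units (the
    base population is a known fraction of the population it represents).
    """

    counts: pd.DataFrame
    scale_factor: float = 1.0

    def margin(self, by: Sequence[str]) -> pd.DataFrame:
        """Sum counts over every index not named in ``by``."""
        return self.counts.groupby(list(by), as_index=False, observed=True)["count"].sum()

    def population_counts(self, by: Sequence[str]) -> pd.DataFrame:
        out = self.margin(by)
        out["count"] = out["count"] * self.scale_factor
        return out


def tabulate(
    results: Sequence[RunResult],
    scale_factor: float = 1.0,
    min_age: int = 65,
) -> OutputCube:
    """Cross-tabulate every run snapshot of the 65+ alive population.

    Counts are exact integers; the disease-count stratum counts the eight
    chronic diseases (dementia is a separate axis of the cube).
    """
    if not results:
        raise ReportingError("no run results to tabulate")
    rows = []
    for res in results:
        if not res.snapshots:
            raise ReportingError(f"run {res.run_index} has no snapshots")
        for year, snap in sorted(res.snapshots.items()):
            alive = snap[snap["alive"] == 1]
            age_years = alive["age_months"].to_numpy() // 12
            older = alive[age_years >= min_age]
            if older.empty:
                continue
            age_years = older["age_months"].to_numpy() // 12
            n_dis = sum(older[d].to_numpy() for d in DISEASES)
            cell = pd.DataFrame(
                {
                    "run": res.run_index,
                    "year": year,
                    "sex": older["sex"].to_numpy(),
                    "age_band": _age_band(age_years),
                    "dependency": combined_dependency(older),
                    "disease_stratum": _disease_stratum(n_dis),
                    "dementia": older["dementia"].to_numpy(),
                }
            )
            rows.append(
                cell.groupby(
                    ["run", "year", "sex", "age_band", "dependency", "disease_stratum", "dementia"],
                    as_index=False,
                    observed=True,
                ).size().rename(columns={"size": "count"})
            )
    counts = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["run", "year", "sex", "age_band", "dependency", "disease_stratum", "dementia", "count"]
    )
    return OutputCube(counts=counts, scale_factor=scale_factor)


def relative_change(n_start: float, n_end: float) -> float:
    """Percent change 100 * (end - start) / start, to one decimal."""
    if n_start == 0:
        raise InputDomainError("relative change undefined for a zero starting count")
    return round_half_away(100.0 * (n_end - n_start) / n_start, 1)


def proportion_of_le(years_state: float, total_le: float) -> float:
    """Share of remaining life expectancy spent in a state, percent, one decimal."""
    if total_le <= 0:
        raise InputDomainError("total life expectancy must be positive")
    return round_half_away(100.0 * years_state / total_le, 1)


@dataclass
class HealthExpectancyRow:
    """Life expectancy at ``from_age`` partitioned across dependency levels."""

    sex: str
    year: Optional[int]
    from_age: int
    total_le: float
    years_by_level: dict[int, float] = field(default_factory=dict)

    def proportion(self, level: int) -> float:
        return proportion_of_le(self.years_by_level[level], self.total_le)


def sullivan(
    prevalence: pd.DataFrame,
    lifetable: LifeTable,
    sex: str,
    from_age: int = 65,
    year: Optional[int] = None,
) -> HealthExpectancyRow:
    """Sullivan's method: partition period LE by cross-sectional prevalence.

    ``prevalence`` has columns ``age``, ``dependency`` (0-3) and
    ``proportion``; the proportions for each age from ``from_age`` to the
    lifetable's terminal age must sum to 1 (tolerance 1e-6).  State
    expectancy is ``sum_x pi_state(x) * L_x / l_from_age``; the state years
    sum to total LE by construction.
    """
    surv = lifetable.survivorship(sex)
    surv = surv[surv.age >= from_age]
    if surv.empty:
        raise InputDomainError(f"lifetable does not reach age {from_age}")
    wide = prevalence.pivot_table(
        index="age", columns="dependency", values="proportion", fill_value=0.0
    ).reindex(columns=range(4), fill_value=0.0)
    needed = surv["age"].to_numpy()
    missing = np.setdiff1d(needed, wide.index.to_numpy())
    if missing.size:
        raise InputDomainError(f"prevalence missing for ages {missing.tolist()}")
    wide = wide.loc[needed]
    sums = wide.sum(axis=1).to_numpy()
    if np.any(np.abs(sums - 1.0) > 1e-6):
        bad = needed[np.argmax(np.abs(sums - 1.0))]
        raise InputDomainError(f"prevalence proportions at age {bad} do not sum to 1")
    l_start = surv["l"].iloc[0]
    L = surv["L"].to_numpy()
    total = float(L.sum() / l_start)
    years = {
        int(level): float((wide[level].to_numpy() * L).sum() / l_start) for level in range(4)
    }
    return HealthExpectancyRow(
        sex=sex, year=year, from_age=from_age, total_le=total, years_by_level=years
    )


def prevalence_from_snapshot(
    snapshot: pd.DataFrame,
    sex_code: int,
    age_min: int,
    age_max: int,
    min_cell: int = 30,
    smooth_window: int = 5,
) -> pd.DataFrame:
    """Single-year-of-age dependency prevalence from one run snapshot.

    Ages whose cell holds fewer than ``min_cell`` alive individuals use a
    centred ``smooth_window``-year moving average of level counts; ages with
    no observations at all inherit the nearest observed age's distribution
    (extrapolating the oldest cells to the terminal age).
    """
    alive = snapshot[(snapshot["alive"] == 1) & (snapshot["sex"] == sex_code)]
    age_years = alive["age_months"].to_numpy() // 12
    dep = combined_dependency(alive)
    ages = np.arange(age_min, age_max + 1)
    counts = np.zeros((ages.size, 4))
    present = (age_years >= age_min) & (age_years <= age_max)
    np.add.at(counts, (age_years[present] - age_min, dep[present]), 1)

    half = smooth_window // 2
    rows = []
    totals = counts.sum(axis=1)
    for i, age in enumerate(ages):
        c = counts[i]
        if totals[i] < min_cell:
            lo, hi = max(0, i - half), min(ages.size, i + half + 1)
            c = counts[lo:hi].sum(axis=0)
        if c.sum() == 0:
            observed = np.flatnonzero(totals > 0)
            if observed.size == 0:
                raise ReportingError("no alive individuals in the requested age range")
            j = observed[np.argmin(np.abs(observed - i))]
            lo, hi = max(0, j - half), min(ages.size, j + half + 1)
            c = counts[lo:hi].sum(axis=0)
        props = c / c.sum()
        for level in range(4):
            rows.append({"age": age, "dependency": level, "proportion": props[level]})
    return pd.DataFrame(rows)


def health_expectancy_from_run(
    result: RunResult,
    year: int,
    lifetable: LifeTable,
    from_age: int = 65,
) -> dict[str, HealthExpectancyRow]:
    """Sullivan rows for both sexes from one run's snapshot of ``year``."""
    if year not in result.snapshots:
        raise ReportingError(f"run {result.run_index} lacks a snapshot for {year}")
    snap = result.snapshots[year]
    out = {}
    for code, sex in ((0, "male"), (1, "female")):
        prev = prevalence_from_snapshot(snap, code, from_age, lifetable.age_max)
        out[sex] = sullivan(prev, lifetable, sex, from_age=from_age, year=year)
    return out


def cohort_trace(
    results: Sequence[RunResult],
    cohort_width: int = 5,
    min_report_age: int = 65,
    run_index: int = 0,
) -> pd.DataFrame:
    """Proportion independent by 5-year birth cohort, sex and output year.

    A cohort-year cell is reported only when every member of the cohort has
    reached ``min_report_age`` in that year; empty cells are emitted as
    missing (NaN), not zero.
    """
    result = next((r for r in results if r.run_index == run_index), None)
    if result is None or len(result.snapshots) < 2:
        raise ReportingError("cohort traces need one run with snapshots at >= 2 years")
    rows = []
    for year, snap in sorted(result.snapshots.items()):
        alive = snap[snap["alive"] == 1]
        age_years = alive["age_months"].to_numpy() // 12
        birth_year = year - age_years
        cohort_start = ((birth_year - 1) // cohort_width) * cohort_width + 1
        dep = combined_dependency(alive)
        frame = pd.DataFrame(
            {
                "sex": alive["sex"].to_numpy(),
                "cohort_start": cohort_start,
                "independent": (dep == 0).astype(float),
                "age": age_years,
            }
        )
        grouped = frame.groupby(["sex", "cohort_start"]).agg(
            proportion_independent=("independent", "mean"),
            n=("independent", "size"),
            youngest_age=("age", "min"),
        ).reset_index()
        # suppress cohorts not wholly 65+ in this year: the youngest possible
        # member of cohort [c, c+4] is aged year - (c + 4)
        grouped = grouped[(year - (grouped["cohort_start"] + cohort_width - 1)) >= min_report_age]
        grouped.loc[grouped["n"] == 0, "proportion_independent"] = np.nan
        grouped["year"] = year
        grouped["cohort"] = grouped["cohort_start"].map(
            lambda c: f"{c}-{c + cohort_width - 1}"
        )
        rows.append(grouped[["year", "sex", "cohort", "proportion_independent", "n"]])
    return pd.concat(rows, ignore_index=True)


def range_over_runs(values_by_run: Sequence[float]) -> tuple[float, float, float]:
    """(headline, min, max): the first run's value plus the range over runs."""
    if len(values_by_run) == 0:
        raise ReportingError("no run values supplied")
    vals = [float(v) for v in values_by_run]
    return vals[0], min(vals), max(vals)
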