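"""Engine mechanics: stepping, mortality, dementia allocation, determinism."""

import numpy as np
import pandas as pd
import pytest

import caresim as cs
from caresim.engine import _philox
from caresim.exceptions import ConfigurationError
from caresim.population import DISEASES, STATE_COLUMNS


def _cohort(n, age_years=65, seed=0):
    """A healthy single-age cohort for oracle experiments."""
    rng = np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "id": np.arange(n),
            "study": "toy",
            "sex": rng.integers(0, 2, n).astype(np.int8),
            "age_months": np.full(n, age_years * 12, dtype=np.int32),
            "education": 1, "occupation": 1, "smoking": 0, "bmi_class": 0,
            "physical_activity": 1,
            **{d: 0 for d in DISEASES},
            "vision": 0, "hearing": 0, "mmse": 30, "cognition": 0,
            "phys_dep": 0, "residence": 0, "dementia": 0, "alive": 1,
            "weight": 1.0,
        }
    )
    return frame


def _constant_prob_modelset(quiet_modelset, overrides):
    """Quiet models with selected transitions set to constant biennial logits."""
    models = []
    for m in quiet_modelset:
        if m.key in overrides:
            coefs = {name: 0.0 for name in m.covariates}
            coefs["intercept"] = overrides[m.key]
            m = cs.TransitionModel(
                m.characteristic, m.from_state, m.to_state, m.direction,
                m.covariates, coefs,
            )
        models.append(m)
    return cs.ModelSet(models)


class TestStepIndividual:
    def test_quiet_month_only_ages(self, quiet_modelset, immortal_lifetable):
        base = _cohort(1)
        state = cs.IndividualState.from_row(base.iloc[0])
        rng = np.random.default_rng(0)
        after = cs.step_individual(state, quiet_modelset, immortal_lifetable, (2014, 1), rng)
        assert after.age_months == state.age_months + 1
        for name, _ in STATE_COLUMNS:
            if name in ("age_months", "study"):
                continue
            assert getattr(after, name) == getattr(state, name), name

    def test_certain_death_freezes_state(self, quiet_modelset):
        frame = cs.generate_lifetable().table[["sex", "age", "survival"]].copy()
        frame["survival"] = 1e-300
        doomed = cs.LifeTable(frame)
        state = cs.IndividualState.from_row(_cohort(1).iloc[0])
        after = cs.step_individual(state, quiet_modelset, doomed, (2014, 1), np.random.default_rng(1))
        assert after.alive == 0
        assert after.age_months == state.age_months  # dead: no ageing

    def test_dead_individual_rejected(self, quiet_modelset, immortal_lifetable):
        state = cs.IndividualState.from_row(_cohort(1).iloc[0])
        state.alive = 0
        with pytest.raises(ConfigurationError):
            cs.step_individual(state, quiet_modelset, immortal_lifetable, (2014, 1), np.random.default_rng(0))

    def test_missing_characteristic_model_is_configuration_error(self, quiet_modelset, immortal_lifetable):
        partial = cs.ModelSet([m for m in quiet_modelset if m.characteristic != "cognition"])
        state = cs.IndividualState.from_row(_cohort(1).iloc[0])
        with pytest.raises(ConfigurationError, match="cognition"):
            cs.step_individual(state, partial, immortal_lifetable, (2014, 1), np.random.default_rng(0))


class TestMarkovOracle:
    def test_two_state_occupancy_matches_matrix_power(self, quiet_modelset, immortal_lifetable):
        # depression on/off with constant monthly probabilities; the engine's
        # occupancy after k months must match the analytic chain distribution
        from scipy.special import logit

        p_on_bi, p_off_bi = 0.35, 0.25
        models = _constant_prob_modelset(
            quiet_modelset,
            {"depression:0>1": float(logit(p_on_bi)), "depression:1>0": float(logit(p_off_bi))},
        )
        p01 = cs.biennial_to_monthly(p_on_bi)
        p10 = cs.biennial_to_monthly(p_off_bi)
        n, months = 10_000, 24
        base = _cohort(n)
        cfg = cs.SimulationConfig(
            start=(2014, 1), end=(2015, 12), output_years=(2015,), snapshot_month=12,
            n_runs=1, master_seed=99,
        )
        dem = cs.generate_dementia_table()
        dem = dem.assign(probability=0.0)
        res = cs.run_simulation(base, models, immortal_lifetable, dem, cfg)
        snap = res[0].snapshots[2015]

        P = np.array([[1 - p01, p01], [p10, 1 - p10]])
        occupancy = np.array([1.0, 0.0]) @ np.linalg.matrix_power(P, months)
        observed = snap["depression"].mean()
        se = np.sqrt(occupancy[1] * (1 - occupancy[1]) / n)
        assert abs(observed - occupancy[1]) < 3 * se


class TestMortalityOracle:
    def test_cohort_survivorship_matches_lifetable(self, quiet_modelset, lifetable, dementia_table):
        # mortality only: survivors to age 65+k track l_{65+k}/l_65
        n = 10_000
        base = _cohort(n, age_years=65)
        base["sex"] = 0
        cfg = cs.SimulationConfig(
            start=(2014, 1), end=(2023, 12), output_years=(2018, 2023), snapshot_month=12,
            n_runs=1, master_seed=123,
        )
        res = cs.run_simulation(base, quiet_modelset, lifetable, dementia_table, cfg)
        surv = lifetable.survivorship("male").set_index("age")["l"]
        for year in (2018, 2023):
            snap = res[0].snapshots[year]
            years_elapsed = (snap["age_months"].max()) // 12 - 65
            expected = surv[65 + years_elapsed] / surv[65]
            observed = snap["alive"].mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(observed - expected) < 3 * se, year


class TestAllocateDementia:
    def test_zero_table_allocates_none(self, base_small, dementia_table):
        table = dementia_table.assign(probability=0.0)
        out = cs.allocate_dementia(base_small, table, np.random.default_rng(0))
        assert (out["dementia"] == 0).all()

    def test_binomial_count_in_single_cell(self, dementia_table):
        n, p = 10_000, 0.37
        pop = _cohort(n, age_years=80)
        table = dementia_table.assign(probability=p)
        out = cs.allocate_dementia(pop, table, np.random.default_rng(7))
        count = out["dementia"].sum()
        assert abs(count - n * p) < 3 * np.sqrt(n * p * (1 - p))

    def test_only_dementia_column_changes(self, base_small, dementia_table):
        out = cs.allocate_dementia(base_small, dementia_table, np.random.default_rng(3))
        for col in base_small.columns:
            if col != "dementia":
                pd.testing.assert_series_equal(out[col], base_small[col])

    def test_uncovered_cell_is_error(self, base_small, dementia_table):
        truncated = dementia_table[dementia_table.age_group != "35-64"]
        with pytest.raises(ConfigurationError):
            cs.allocate_dementia(base_small, truncated, np.random.default_rng(0))


@pytest.fixture(scope="module")
def short_cfg():
    return cs.SimulationConfig(
        start=(2014, 1), end=(2017, 12), output_years=(2015, 2017),
        snapshot_month=12, n_runs=2, master_seed=555,
    )


@pytest.fixture(scope="module")
def short_run(base_small, truth_models, lifetable, dementia_table, short_cfg):
    return cs.run_simulation(base_small, truth_models, lifetable, dementia_table, short_cfg)


class TestRunSimulation:
    def test_identical_seed_is_byte_identical(
        self, base_small, truth_models, lifetable, dementia_table, short_cfg, short_run, tmp_path
    ):
        again = cs.run_simulation(base_small, truth_models, lifetable, dementia_table, short_cfg)
        for r1, r2 in zip(short_run, again):
            for year in r1.snapshots:
                p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
                r1.snapshots[year].to_csv(p1, index=False)
                r2.snapshots[year].to_csv(p2, index=False)
                assert p1.read_bytes() == p2.read_bytes()
            pd.testing.assert_frame_equal(r1.events, r2.events)

    def test_different_seed_differs(self, base_small, truth_models, lifetable, dementia_table, short_cfg, short_run):
        cfg2 = cs.SimulationConfig(
            start=short_cfg.start, end=short_cfg.end, output_years=short_cfg.output_years,
            n_runs=1, master_seed=556,
        )
        other = cs.run_simulation(base_small, truth_models, lifetable, dementia_table, cfg2)
        assert not other[0].snapshots[2017].equals(short_run[0].snapshots[2017])

    def test_population_accounting(self, short_run, base_small):
        # snapshots fall at December, so cumulative yearly deaths reconcile
        # exactly: alive + deaths-to-date = base size, nobody created or lost
        for res in short_run:
            for year in sorted(res.snapshots):
                snap = res.snapshots[year]
                assert len(snap) == len(base_small)
                deaths_to_date = res.events.loc[res.events.year <= year, "deaths"].sum()
                assert (snap["alive"] == 1).sum() + deaths_to_date == len(base_small)

    def test_dead_individuals_frozen_between_snapshots(self, short_run):
        res = short_run[0]
        early, late = res.snapshots[2015], res.snapshots[2017]
        dead_early = early[early["alive"] == 0]
        frozen_cols = [c for c in early.columns if c not in ("dementia",)]
        pd.testing.assert_frame_equal(
            late.loc[dead_early.index, frozen_cols], dead_early[frozen_cols]
        )

    def test_snapshot_dependency_levels_partition_alive(self, short_run):
        from caresim.outputs import combined_dependency

        snap = short_run[0].snapshots[2017]
        alive = snap[snap["alive"] == 1]
        dep = combined_dependency(alive)
        assert set(np.unique(dep)) <= {0, 1, 2, 3}
        assert len(dep) == len(alive)

    def test_zero_everything_just_ages_population(self, base_small, quiet_modelset, immortal_lifetable, dementia_table):
        cfg = cs.SimulationConfig(
            start=(2014, 1), end=(2015, 12), output_years=(2015,), snapshot_month=12,
            n_runs=1, master_seed=1,
        )
        zero_dem = dementia_table.assign(probability=0.0)
        res = cs.run_simulation(base_small, quiet_modelset, immortal_lifetable, zero_dem, cfg)
        snap = res[0].snapshots[2015]
        months_elapsed = 24  # Jan 2014 .. Dec 2015 inclusive
        assert (snap["age_months"].to_numpy() == base_small["age_months"].to_numpy() + months_elapsed).all()
        for col in snap.columns:
            if col in ("age_months", "id", "study", "weight"):
                continue
            assert (snap[col].to_numpy() == base_small[col].to_numpy()).all(), col

    def test_raising_incidence_raises_disease_burden(
        self, base_small, truth_models, lifetable, dementia_table
    ):
        cfg = cs.SimulationConfig(
            start=(2014, 1), end=(2017, 12), output_years=(2017,), n_runs=1, master_seed=77,
        )
        boosted_models = []
        for m in truth_models:
            coefs = dict(m.coefficients)
            if m.characteristic in DISEASES and m.direction == "incidence":
                coefs["intercept"] = coefs["intercept"] + 1.0
            boosted_models.append(
                cs.TransitionModel(m.characteristic, m.from_state, m.to_state,
                                   m.direction, m.covariates, coefs)
            )
        low = cs.run_simulation(base_small, truth_models, lifetable, dementia_table, cfg)
        high = cs.run_simulation(base_small, cs.ModelSet(boosted_models), lifetable, dementia_table, cfg)

        def burden(res):
            snap = res[0].snapshots[2017]
            alive = snap[snap["alive"] == 1]
            return sum(alive[d].mean() for d in DISEASES)

        assert burden(high) >= burden(low)

    def test_missing_model_for_characteristic_rejected(
        self, base_small, truth_models, lifetable, dementia_table
    ):
        partial = cs.ModelSet([m for m in truth_models if m.characteristic != "phys_dep"])
        with pytest.raises(ConfigurationError, match="phys_dep"):
            cs.run_simulation(base_small, partial, lifetable, dementia_table,
                              cs.SimulationConfig(n_runs=1))

    def test_update_order_must_be_permutation(self):
        with pytest.raises(ConfigurationError):
            cs.SimulationConfig(update_order=("chd", "stroke"))

    def test_philox_streams_are_stable(self):
        a = _philox(1, 2, 3, 4).random(5)
        b = _philox(1, 2, 3, 4).random(5)
        c = _philox(1, 2, 3, 5).random(5)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)
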