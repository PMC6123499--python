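"""Discrete-time microsimulation engine.

Every individual in the base population is advanced month by month (default
horizon January 2014 – December 2042).  Within a month each stochastic
characteristic is updated in a configured order (behaviours -> diseases ->
sensory impairments -> cognition -> physical dependency), with within-month
updated values visible to later characteristics; a state changes when its
monthly transition probability strictly exceeds a Uniform(0,1) draw.  Worse
("incidence") moves are offered before recovery moves, and a characteristic
moves at most one step per month.  Mortality is then applied from age-sex
annual survival probabilities rescaled to months, and survivors age one
month.  Age, sex, education and occupation never transition stochastically.

Randomness is counter-based: each (run, month, stream) triple seeds its own
Philox stream, where a stream is one transition model or the mortality draw,
and uniforms are indexed by individual position.  Results are therefore
independent of the iteration order over individuals and byte-identical for
a given master seed.

Dementia is never simulated in the monthly loop; it is allocated to each
output-year snapshot from a probability table by age group, cognition
category and residence (:func:`allocate_dementia`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import dementia_age_group
from .exceptions import ConfigurationError
from .lifetable import LifeTable
from .population import STATE_COLUMNS, IndividualState, validate_population
from .transitions import (
    STOCHASTIC_CHARACTERISTICS,
    ModelSet,
    TransitionModel,
    annual_survival_to_monthly,
)

__all__ = [
    "SimulationConfig",
    "RunResult",
    "step_individual",
    "allocate_dementia",
    "run_simulation",
]

_MORTALITY_STREAM = "mortality"
_DEMENTIA_STREAM_BASE = 1_000_000


@dataclass
class SimulationConfig:
    """Run-level settings for :func:`run_simulation`."""

    start: tuple[int, int] = (2014, 1)
    end: tuple[int, int] = (2042, 12)
    output_years: tuple[int, ...] = (2015, 2025, 2035)
    #: calendar month (1-12) whose end-of-month state is snapshotted in an
    #: output year; 6 gives a mid-year population
    snapshot_month: int = 6
    n_runs: int = 10
    master_seed: int = 20140101
    update_order: tuple[str, ...] = STOCHASTIC_CHARACTERISTICS

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ConfigurationError("simulation start must precede end")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        if sorted(self.update_order) != sorted(STOCHASTIC_CHARACTERISTICS):
            raise ConfigurationError(
                "update_order must be a permutation of the stochastic characteristics"
            )
        if not 1 <= self.snapshot_month <= 12:
            raise ConfigurationError("snapshot_month must be 1..12")
        bad = [y for y in self.output_years if not self.start[0] <= y <= self.end[0]]
        if bad:
            raise ConfigurationError(f"output years outside horizon: {bad}")

    def months(self):
        """Yield (year, month) pairs over the horizon, inclusive."""
        y, m = self.start
        while (y, m) <= self.end:
            yield y, m
            m += 1
            if m == 13:
                y, m = y + 1, 1


@dataclass
class RunResult:
    """One replicate: snapshots (dementia allocated) plus event counts."""

    run_index: int
    master_seed: int
    snapshots: dict[int, pd.DataFrame] = field(default_factory=dict)
    events: Optional[pd.DataFrame] = None  # columns year, deaths, transitions


# ---------------------------------------------------------------------------
# random streams
# ---------------------------------------------------------------------------
def _philox(master_seed: int, *spawn_key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in spawn_key))
    return np.random.Generator(np.random.Philox(ss))


def _ordered_models(models: ModelSet, update_order: Sequence[str]) -> list[tuple[str, list[TransitionModel]]]:
    """Per characteristic, its models: incidence (ascending from-state) then recovery."""
    out = []
    for char in update_order:
        chosen = [m for m in models if m.characteristic == char]
        chosen.sort(key=lambda m: (m.direction != "incidence", m.from_state))
        out.append((char, chosen))
    return out


# ---------------------------------------------------------------------------
# monthly kernel
# ---------------------------------------------------------------------------
def _advance_month(
    arrays: dict[str, np.ndarray],
    ordered_models: list[tuple[str, list[TransitionModel]]],
    lifetable: LifeTable,
    draw: Callable[[int, int], np.ndarray],
) -> tuple[int, int]:
    """Advance every individual one month in place.

    ``draw(stream_index, n)`` returns n uniforms for one stream; stream 0 is
    mortality and stream ``1+j`` the j-th model in ``ordered_models`` order.
    Returns (n_transitions, n_deaths).
    """
    alive = arrays["alive"].astype(bool)
    n = alive.size
    n_transitions = 0
    stream = 1
    for char, models in ordered_models:
        current = arrays[char]
        moved = np.zeros(n, dtype=bool)
        for model in models:
            u = draw(stream, n)
            stream += 1
            at_risk = alive & ~moved & (current == model.from_state)
            if at_risk.any():
                p = model.monthly_probability(arrays)
                move = at_risk & (p > u)
                if move.any():
                    current[move] = model.to_state
                    moved |= move
                    n_transitions += int(move.sum())
        if char == "cognition":
            # keep the MMSE score inside the (possibly new) band so that
            # snapshots remain internally consistent
            _sync_mmse(arrays, moved)

    u = draw(0, n)
    age_years = arrays["age_months"] // 12
    s_month = annual_survival_to_monthly(lifetable.annual_survival(arrays["sex"], age_years))
    die = alive & ((1.0 - s_month) > u)
    arrays["alive"][die] = 0
    still_alive = alive & ~die
    arrays["age_months"][still_alive] += 1
    return n_transitions, int(die.sum())


_BAND_EDGE = {0: 27, 1: 21, 2: 10, 3: 0}


def _sync_mmse(arrays: dict[str, np.ndarray], moved: np.ndarray) -> None:
    # deterministic: a changed band sets MMSE to the band's top score
    if moved.any():
        cog = arrays["cognition"][moved]
        top = np.select([cog == 0, cog == 1, cog == 2], [30, 26, 20], default=9)
        arrays["mmse"][moved] = top


def _check_models(models: ModelSet, update_order: Sequence[str]) -> None:
    missing = [c for c in update_order if not any(m.characteristic == c for m in models)]
    if missing:
        raise ConfigurationError(
            f"no transition model supplied for stochastic characteristic(s): {missing}"
        )


def step_individual(
    state: IndividualState,
    models: ModelSet,
    lifetable: LifeTable,
    month: tuple[int, int],
    rng: np.random.Generator,
    update_order: Sequence[str] = STOCHASTIC_CHARACTERISTICS,
) -> IndividualState:
    """Advance a single alive individual one month.

    The scalar counterpart of the vectorised engine: one uniform is drawn
    from ``rng`` per transition model (in update order) and one for
    mortality, exactly as in :func:`run_simulation`'s per-month kernel.
    """
    if not state.alive:
        raise ConfigurationError("cannot step a dead individual")
    _check_models(models, update_order)
    arrays = {
        name: np.array([getattr(state, name)]) for name, _ in STATE_COLUMNS if name != "study"
    }
    ordered = _ordered_models(models, update_order)
    n_streams = 1 + sum(len(ms) for _, ms in ordered)
    uniforms = rng.random(n_streams)

    def draw(stream: int, n: int) -> np.ndarray:
        return uniforms[stream : stream + 1]

    _advance_month(arrays, ordered, lifetable, draw)
    out: dict = {"study": state.study, "weight": float(arrays["weight"][0])}
    for name in arrays:
        if name != "weight":
            out[name] = int(arrays[name][0])
    return IndividualState(**out)


def allocate_dementia(
    population: pd.DataFrame,
    dementia_table: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw dementia status per individual from the allocation table.

    Applied to snapshots only, never inside the monthly loop.  Only the
    ``dementia`` column changes; every individual must map to exactly one
    (age group, cognition, residence) cell.
    """
    out = population.copy()
    keyed = dementia_table.set_index(["age_group", "cognition", "residence"])["probability"]
    groups = dementia_age_group(out["age_months"].to_numpy() / 12.0)
    try:
        probs = keyed.loc[
            list(zip(groups, out["cognition"].astype(int), out["residence"].astype(int)))
        ].to_numpy()
    except KeyError as exc:
        raise ConfigurationError(f"dementia table does not cover cell {exc.args[0]!r}") from None
    out["dementia"] = (rng.random(len(out)) < probs).astype(np.int8)
    return out


def run_simulation(
    base_population: pd.DataFrame,
    models: ModelSet,
    lifetable: LifeTable,
    dementia_table: pd.DataFrame,
    config: Optional[SimulationConfig] = None,
) -> list[RunResult]:
    """Execute ``config.n_runs`` independent replicates of the full horizon.

    Each run advances every individual month by month, snapshots the
    population at the configured month of each output year, allocates
    dementia to the snapshot, and logs yearly transition and death counts.
    Identical ``master_seed`` gives byte-identical results.
    """
    config = config or SimulationConfig()
    base = validate_population(base_population.copy(), context="base population")
    _check_models(models, config.update_order)
    ordered = _ordered_models(models, config.update_order)
    results = []
    for run_idx in range(config.n_runs):
        arrays = {
            name: base[name].to_numpy().copy()
            for name, _ in STATE_COLUMNS
            if name != "study"
        }
        study = base["study"].to_numpy()
        result = RunResult(run_index=run_idx, master_seed=config.master_seed)
        yearly: dict[int, dict[str, int]] = {}
        for month_idx, (year, month) in enumerate(config.months()):
            def draw(stream: int, n: int, _m=month_idx) -> np.ndarray:
                return _philox(config.master_seed, run_idx, _m, stream).random(n)

            n_trans, n_deaths = _advance_month(arrays, ordered, lifetable, draw)
            rec = yearly.setdefault(year, {"transitions": 0, "deaths": 0})
            rec["transitions"] += n_trans
            rec["deaths"] += n_deaths
            if year in config.output_years and month == config.snapshot_month:
                snap = pd.DataFrame({name: arrays[name].copy() for name in arrays})
                snap["study"] = study
                snap = snap[[name for name, _ in STATE_COLUMNS]]
                dem_rng = _philox(config.master_seed, run_idx, _DEMENTIA_STREAM_BASE + year)
                result.snapshots[year] = allocate_dementia(snap, dementia_table, dem_rng)
        result.events = pd.DataFrame(
            [{"year": y, **rec} for y, rec in sorted(yearly.items())]
        )
        results.append(result)
    return results
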