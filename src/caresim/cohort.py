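"""Synthetic cohort generation with known ground truth.

Everything the real inputs of a dependency microsimulation would provide is
generated here with a recorded parameterisation:

* :func:`generate_study_extract` — one longitudinal study's contribution: a
  baseline cross-section of individuals aged 35+ (older entry ages for the
  ageing-specific studies) with study weights, plus a 2-year follow-up
  produced by applying known transition logits, with missing-at-random
  attrition.
* :func:`build_base_population` — the pooled, reweighted (iterative
  proportional fitting), cloned-to-unit-weight and subsampled base
  population the engine starts from.
* :func:`generate_dementia_table` — allocation probabilities by age group,
  cognition category and residence for the post-simulation dementia draw.

The generating parameters (:class:`GroundTruthParams`) are serialisable and
are written beside every dataset, so parameter-recovery tests can compare
fitted transition models against the exact logits that produced the panel.

Baseline prevalences follow logistic age-sex gradients chosen to resemble an
English mid-2010s adult population: hypertension and arthritis common and
steeply age-graded, stroke and coronary disease rarer with male excess,
depression commoner in women, sensory and cognitive impairment and physical
dependency rising sharply after 75, care-home residence concentrated among
the very old with high dependency or severe cognitive impairment.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .exceptions import ConfigurationError, RakingError
from .population import DISEASES, STATE_COLUMNS, validate_population
from .transitions import TRANSITIONS, TransitionSpec

__all__ = [
    "GroundTruthParams",
    "default_ground_truth",
    "generate_study_extract",
    "truth_modelset",
    "build_base_population",
    "generate_dementia_table",
    "default_target_margins",
    "rake_weights",
    "AGE_BANDS_RAKING",
]

MAX_BASELINE_AGE = 99

#: 5-year bands used when raking study weights to population margins.
AGE_BANDS_RAKING: tuple[tuple[int, int], ...] = tuple(
    (lo, lo + 4) for lo in range(35, 85, 5)
) + ((85, 150),)


def age_band_label(age_years, bands=AGE_BANDS_RAKING) -> np.ndarray:
    """Map (possibly fractional) ages to band labels like ``'35-39'`` / ``'85+'``."""
    age = np.floor(np.asarray(age_years, dtype=float)).astype(int)
    labels = np.empty(age.shape, dtype=object)
    for lo, hi in bands:
        name = f"{lo}+" if hi >= 150 else f"{lo}-{hi}"
        labels[(age >= lo) & (age <= hi)] = name
    if (labels == None).any():  # noqa: E711 - elementwise comparison intended
        bad = age[labels == None][0]  # noqa: E711
        raise RakingError(f"age {bad} outside every age band")
    return labels


# ---------------------------------------------------------------------------
# ground truth parameterisation
# ---------------------------------------------------------------------------
def _coef(intercept=0.0, age_c=0.0, age_c2=0.0, female=0.0, **extra) -> dict[str, float]:
    d = {"intercept": intercept, "age_c": age_c, "age_c2": age_c2, "female": female}
    d.update(extra)
    return d


@dataclass
class GroundTruthParams:
    """Every constant behind the synthetic data, in one serialisable object.

    Logit coefficient dictionaries use the covariate names of
    :mod:`caresim.population` (``age_c`` = age-65 in years, ``age_c2`` its
    square / 100).  ``transitions`` maps registry keys ``char:from>to`` to
    2-year logits.
    """

    # marginal age weights, piecewise-linear between (age, weight) anchors
    age_anchors: tuple = ((35, 1.0), (55, 0.95), (65, 0.80), (75, 0.55), (85, 0.25), (95, 0.05), (105, 0.004))
    p_female: dict = field(default_factory=lambda: _coef(0.04, 0.0, 0.0))
    p_female_old_age_slope: float = 0.012  # extra logit per year above 65
    education_high: dict = field(default_factory=lambda: _coef(0.65, -0.035))
    education_low_given_not_high: dict = field(default_factory=lambda: _coef(-0.35, 0.022))
    occupation_nonmanual_by_education: tuple = (0.35, 0.55, 0.80)
    smoking_current: dict = field(default_factory=lambda: _coef(-1.35, -0.035))
    smoking_former_given_not_current: dict = field(default_factory=lambda: _coef(-0.25, 0.025))
    bmi_overweight: dict = field(default_factory=lambda: _coef(-0.30, 0.002))
    bmi_obese_given_not_over: dict = field(default_factory=lambda: _coef(-0.75, -0.003))
    activity_low: dict = field(default_factory=lambda: _coef(-1.40, 0.045))
    activity_high_given_not_low: dict = field(default_factory=lambda: _coef(0.20, -0.030))
    diseases: dict = field(
        default_factory=lambda: {
            "chd": _coef(-2.2, 0.050, 0.0, -0.50),
            "stroke": _coef(-3.2, 0.060, 0.0, -0.20),
            "hypertension": _coef(-0.2, 0.040, -0.20, -0.10),
            "diabetes": _coef(-2.1, 0.030, 0.0, -0.15),
            "arthritis": _coef(-1.2, 0.050, -0.10, 0.50),
            "cancer": _coef(-2.8, 0.040, 0.0, 0.0),
            "respiratory": _coef(-2.0, 0.015, 0.0, 0.10),
            "depression": _coef(-1.9, -0.010, 0.0, 0.50),
        }
    )
    vision_some: dict = field(default_factory=lambda: _coef(-2.2, 0.055))
    vision_severe_given_some: dict = field(default_factory=lambda: _coef(-2.0, 0.030))
    hearing_some: dict = field(default_factory=lambda: _coef(-1.9, 0.060, 0.0, -0.30))
    hearing_severe_given_some: dict = field(default_factory=lambda: _coef(-2.2, 0.030))
    cognition_ge_mild: dict = field(default_factory=lambda: _coef(-2.6, 0.090))
    cognition_ge_moderate: dict = field(default_factory=lambda: _coef(-1.7, 0.050))
    cognition_severe: dict = field(default_factory=lambda: _coef(-1.6, 0.030))
    mmse_normal_band_probs: tuple = (0.10, 0.20, 0.30, 0.40)  # scores 27..30
    phys_dep_ge_low: dict = field(default_factory=lambda: _coef(-2.4, 0.075, 0.0, 0.10, n_diseases=0.25))
    phys_dep_ge_medium: dict = field(default_factory=lambda: _coef(-1.6, 0.040, 0.0, 0.0, n_diseases=0.10))
    phys_dep_high: dict = field(default_factory=lambda: _coef(-0.8, 0.030))
    residence_care_home: dict = field(
        default_factory=lambda: _coef(-5.5, 0.090, 0.0, 0.10, phys_dep_high=1.2, cognition_severe=1.0)
    )
    #: 2-year transition logits, keyed like the registry (zeros filled for
    #: any registry covariate not listed)
    transitions: dict = field(default_factory=lambda: _default_transition_truth())
    attrition_rate: float = 0.10
    attrition_age_slope: float = 0.008
    attrition_female: float = -0.10
    #: study label -> (default n, minimum entry age, lognormal weight mu/sigma)
    studies: dict = field(
        default_factory=lambda: {
            "household-panel": {"n": 16000, "min_age": 35, "weight_mu": 0.0, "weight_sigma": 0.35},
            "ageing-50plus": {"n": 5200, "min_age": 50, "weight_mu": 0.15, "weight_sigma": 0.30},
            "ageing-65plus": {"n": 3200, "min_age": 65, "weight_mu": 0.30, "weight_sigma": 0.25},
        }
    )
    dementia_base: tuple = (  # probability by cognition band within age 65-74, community
        (0.002, 0.02, 0.22, 0.60)
    )
    dementia_age_multiplier: dict = field(
        default_factory=lambda: {"35-64": 0.25, "65-74": 1.0, "75-84": 1.8, "85+": 2.6}
    )
    dementia_care_home_logit_shift: float = 1.0

    def to_dict(self) -> dict:
        def convert(v):
            if isinstance(v, dict):
                return {k: convert(x) for k, x in v.items()}
            if isinstance(v, tuple):
                return [convert(x) for x in v]
            return v

        return {k: convert(v) for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthParams":
        def detuple(v):
            if isinstance(v, list):
                return tuple(detuple(x) for x in v)
            if isinstance(v, dict):
                return {k: detuple(x) for k, x in v.items()}
            return v

        kwargs = {k: detuple(v) for k, v in d.items()}
        # dicts of coefficients must stay dicts, not tuples
        obj = cls()
        for k, v in kwargs.items():
            if isinstance(getattr(obj, k), dict) and isinstance(v, tuple):
                v = dict(v)
            setattr(obj, k, v)
        return obj

    def copy(self) -> "GroundTruthParams":
        return copy.deepcopy(self)


def _default_transition_truth() -> dict[str, dict[str, float]]:
    t: dict[str, dict[str, float]] = {
        "smoking:2>1": _coef(-1.4, 0.020),
        "smoking:1>2": _coef(-3.0, -0.020),
        "bmi_class:0>1": _coef(-2.2, 0.0, 0.0, 0.0, low_activity=0.20),
        "bmi_class:1>2": _coef(-2.6, -0.005, 0.0, 0.10, low_activity=0.30),
        "bmi_class:1>0": _coef(-2.8, 0.005),
        "bmi_class:2>1": _coef(-2.5, 0.005),
        "physical_activity:2>1": _coef(-1.2, 0.030),
        "physical_activity:1>0": _coef(-1.8, 0.045),
        "physical_activity:1>2": _coef(-2.0, -0.030),
        "physical_activity:0>1": _coef(-2.2, -0.030),
        "chd:0>1": _coef(-3.8, 0.045, 0.0, -0.40, current_smoker=0.40, obese=0.30, low_activity=0.25),
        "stroke:0>1": _coef(-4.3, 0.055, 0.0, -0.10, current_smoker=0.40, obese=0.20, low_activity=0.20),
        "hypertension:0>1": _coef(-2.9, 0.030, 0.0, -0.05, current_smoker=0.10, obese=0.45, low_activity=0.20),
        "diabetes:0>1": _coef(-3.9, 0.020, 0.0, -0.10, current_smoker=0.10, obese=0.70, low_activity=0.30),
        "arthritis:0>1": _coef(-3.2, 0.035, 0.0, 0.35),
        "cancer:0>1": _coef(-4.0, 0.045, 0.0, -0.05),
        "respiratory:0>1": _coef(-4.0, 0.020, 0.0, 0.05, current_smoker=0.60),
        "depression:0>1": _coef(-3.6, -0.005, 0.0, 0.45),
        "depression:1>0": _coef(0.30, -0.015, 0.0, -0.10),
        "vision:0>1": _coef(-3.4, 0.050),
        "vision:1>2": _coef(-3.2, 0.040),
        "vision:1>0": _coef(-2.3, -0.020),
        "vision:2>1": _coef(-3.0, -0.020),
        "hearing:0>1": _coef(-3.2, 0.055, 0.0, -0.20),
        "hearing:1>2": _coef(-3.3, 0.040),
        "hearing:1>0": _coef(-2.6, -0.020),
        "hearing:2>1": _coef(-3.2, -0.020),
        "cognition:0>1": _coef(-3.3, 0.080),
        "cognition:1>2": _coef(-2.8, 0.060),
        "cognition:2>3": _coef(-2.4, 0.050),
        "cognition:1>0": _coef(-1.2, -0.040),
        "cognition:2>1": _coef(-2.2, -0.030),
        "phys_dep:0>1": _coef(-3.0, 0.070, 0.0, 0.10, n_diseases=0.22, cognitive_impairment=0.35, low_education=0.20),
        "phys_dep:1>2": _coef(-2.7, 0.050, 0.0, 0.05, n_diseases=0.15, cognitive_impairment=0.30, low_education=0.10),
        "phys_dep:2>3": _coef(-2.2, 0.050, 0.0, 0.05, n_diseases=0.10, cognitive_impairment=0.30, low_education=0.10),
        "phys_dep:1>0": _coef(-0.9, -0.050, 0.0, -0.30, n_diseases=-0.15, cognitive_impairment=-0.30, low_education=-0.10),
        "phys_dep:2>1": _coef(-1.6, -0.040, 0.0, -0.25, n_diseases=-0.10, cognitive_impairment=-0.25, low_education=-0.10),
        "phys_dep:3>2": _coef(-2.0, -0.040, 0.0, -0.25, n_diseases=-0.10, cognitive_impairment=-0.25, low_education=-0.10),
    }
    return t


def default_ground_truth() -> GroundTruthParams:
    return GroundTruthParams()


def truth_modelset(params: Optional[GroundTruthParams] = None):
    """The ground-truth transition logits packaged as a fitted-model set.

    Lets the engine run on the exact generating parameters (no estimation
    step), which is how oracle experiments isolate simulation error from
    estimation error.  Registry transitions without truth coefficients get
    an intercept of -50 (a structural never-happens).
    """
    from .transitions import TRANSITIONS, ModelSet, TransitionModel

    params = params or default_ground_truth()
    models = []
    for spec in TRANSITIONS:
        coefs = params.transitions.get(spec.key)
        if coefs is None:
            coefs = {"intercept": -50.0}
        full = {name: float(coefs.get(name, 0.0)) for name in spec.covariates}
        for name, value in coefs.items():
            if name not in full and value != 0.0:
                full[name] = float(value)
        models.append(
            TransitionModel(
                characteristic=spec.characteristic,
                from_state=spec.from_state,
                to_state=spec.to_state,
                direction=spec.direction,
                covariates=tuple(full),
                coefficients=full,
            )
        )
    return ModelSet(models)


def _validate_params(params: GroundTruthParams) -> None:
    registry_keys = {s.key for s in TRANSITIONS}
    unknown = set(params.transitions) - registry_keys
    if unknown:
        raise ConfigurationError(f"transition truth for unknown keys: {sorted(unknown)}")
    if not 0 <= params.attrition_rate < 1:
        raise ConfigurationError("attrition_rate must lie in [0, 1)")
    for label, s in params.studies.items():
        if s["n"] < 1 or s["min_age"] < 35:
            raise ConfigurationError(f"invalid study spec for {label!r}")


# ---------------------------------------------------------------------------
# baseline generation
# ---------------------------------------------------------------------------
def _logit_prob(coefs: dict[str, float], frame) -> np.ndarray:
    from .population import compute_covariate

    eta = np.zeros(len(frame["age_months"]))
    for name, beta in coefs.items():
        if beta == 0.0:
            continue
        if name == "phys_dep_high":
            x = (np.asarray(frame["phys_dep"]) == 3).astype(float)
        elif name == "cognition_severe":
            x = (np.asarray(frame["cognition"]) == 3).astype(float)
        else:
            x = compute_covariate(name, frame)
        eta = eta + beta * x
    return expit(eta)


def _draw_age_years(rng, n: int, min_age: int, params: GroundTruthParams) -> np.ndarray:
    ages = np.arange(min_age, MAX_BASELINE_AGE + 1)
    xs = [a for a, _ in params.age_anchors]
    ws = [w for _, w in params.age_anchors]
    weights = np.interp(ages, xs, ws)
    weights = np.clip(weights, 1e-6, None)
    return rng.choice(ages, size=n, p=weights / weights.sum())


def generate_baseline(
    n: int, study_label: str, params: GroundTruthParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` baseline individuals for one study."""
    study = params.studies.get(study_label, {"min_age": 35, "weight_mu": 0.0, "weight_sigma": 0.3})
    age_years = _draw_age_years(rng, n, int(study["min_age"]), params)
    age_months = age_years * 12 + rng.integers(0, 12, size=n)
    frame: dict[str, np.ndarray] = {"age_months": age_months.astype(np.int32)}

    eta_f = _logit_prob(params.p_female, frame)
    extra = params.p_female_old_age_slope * np.clip(age_years - 65, 0, None)
    p_f = expit(logit(np.clip(eta_f, 1e-9, 1 - 1e-9)) + extra)
    frame["sex"] = (rng.random(n) < p_f).astype(np.int8)

    p_high = _logit_prob(params.education_high, frame)
    is_high = rng.random(n) < p_high
    p_low = _logit_prob(params.education_low_given_not_high, frame)
    is_low = ~is_high & (rng.random(n) < p_low)
    frame["education"] = np.where(is_high, 2, np.where(is_low, 0, 1)).astype(np.int8)

    p_nm = np.asarray(params.occupation_nonmanual_by_education)[frame["education"]]
    frame["occupation"] = (rng.random(n) < p_nm).astype(np.int8)

    p_cur = _logit_prob(params.smoking_current, frame)
    cur = rng.random(n) < p_cur
    p_former = _logit_prob(params.smoking_former_given_not_current, frame)
    former = ~cur & (rng.random(n) < p_former)
    frame["smoking"] = np.where(cur, 2, np.where(former, 1, 0)).astype(np.int8)

    p_over = _logit_prob(params.bmi_overweight, frame)
    over = rng.random(n) < p_over
    p_ob = _logit_prob(params.bmi_obese_given_not_over, frame)
    obese = ~over & (rng.random(n) < p_ob)
    frame["bmi_class"] = np.where(obese, 2, np.where(over, 1, 0)).astype(np.int8)

    p_low_act = _logit_prob(params.activity_low, frame)
    low_act = rng.random(n) < p_low_act
    p_high_act = _logit_prob(params.activity_high_given_not_low, frame)
    high_act = ~low_act & (rng.random(n) < p_high_act)
    frame["physical_activity"] = np.where(low_act, 0, np.where(high_act, 2, 1)).astype(np.int8)

    for d in DISEASES:
        frame[d] = (rng.random(n) < _logit_prob(params.diseases[d], frame)).astype(np.int8)

    for sense, p_some_c, p_sev_c in (
        ("vision", params.vision_some, params.vision_severe_given_some),
        ("hearing", params.hearing_some, params.hearing_severe_given_some),
    ):
        some = rng.random(n) < _logit_prob(p_some_c, frame)
        severe = some & (rng.random(n) < _logit_prob(p_sev_c, frame))
        frame[sense] = np.where(severe, 2, np.where(some, 1, 0)).astype(np.int8)

    ge_mild = rng.random(n) < _logit_prob(params.cognition_ge_mild, frame)
    ge_mod = ge_mild & (rng.random(n) < _logit_prob(params.cognition_ge_moderate, frame))
    severe = ge_mod & (rng.random(n) < _logit_prob(params.cognition_severe, frame))
    cognition = np.where(severe, 3, np.where(ge_mod, 2, np.where(ge_mild, 1, 0))).astype(np.int8)
    frame["cognition"] = cognition
    mmse = np.empty(n, dtype=np.int16)
    mmse[cognition == 0] = rng.choice(
        np.arange(27, 31), size=int((cognition == 0).sum()), p=params.mmse_normal_band_probs
    )
    mmse[cognition == 1] = rng.integers(21, 27, size=int((cognition == 1).sum()))
    mmse[cognition == 2] = rng.integers(10, 21, size=int((cognition == 2).sum()))
    mmse[cognition == 3] = rng.integers(0, 10, size=int((cognition == 3).sum()))
    frame["mmse"] = mmse

    ge_low = rng.random(n) < _logit_prob(params.phys_dep_ge_low, frame)
    ge_med = ge_low & (rng.random(n) < _logit_prob(params.phys_dep_ge_medium, frame))
    high = ge_med & (rng.random(n) < _logit_prob(params.phys_dep_high, frame))
    frame["phys_dep"] = np.where(high, 3, np.where(ge_med, 2, np.where(ge_low, 1, 0))).astype(np.int8)

    frame["residence"] = (rng.random(n) < _logit_prob(params.residence_care_home, frame)).astype(np.int8)
    frame["dementia"] = np.zeros(n, dtype=np.int8)
    frame["alive"] = np.ones(n, dtype=np.int8)
    frame["weight"] = rng.lognormal(study["weight_mu"], study["weight_sigma"], size=n)
    frame["id"] = np.arange(n, dtype=np.int64)
    frame["study"] = np.full(n, study_label, dtype=object)

    df = pd.DataFrame(frame)
    return validate_population(df, context=f"baseline[{study_label}]")


def _truth_biennial_probability(
    params: GroundTruthParams, spec: TransitionSpec, frame
) -> np.ndarray:
    coefs = params.transitions.get(spec.key)
    if coefs is None:
        return np.zeros(len(frame["age_months"]))
    full = {name: coefs.get(name, 0.0) for name in set(spec.covariates) | set(coefs)}
    return _logit_prob(full, frame)


def apply_truth_transitions(
    baseline: pd.DataFrame, params: GroundTruthParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Simulate the 2-year follow-up state from the ground-truth logits.

    Probabilities are evaluated on the *baseline* frame (the quantity the
    transition fits estimate).  Each characteristic moves at most one
    severity step per wave; where both a worsening and a recovery step leave
    the same state, worsening is drawn first and recovery only offered to
    those who did not worsen.
    """
    follow = baseline.copy()
    by_char: dict[str, list[TransitionSpec]] = {}
    for spec in TRANSITIONS:
        by_char.setdefault(spec.characteristic, []).append(spec)
    for char, specs in by_char.items():
        current = baseline[char].to_numpy()
        new = current.copy()
        moved = np.zeros(len(baseline), dtype=bool)
        ordered = [s for s in specs if s.direction == "incidence"] + [
            s for s in specs if s.direction == "recovery"
        ]
        for spec in ordered:
            at_risk = (current == spec.from_state) & ~moved
            if not at_risk.any():
                continue
            p = _truth_biennial_probability(params, spec, baseline)
            move = at_risk & (rng.random(len(baseline)) < p)
            new[move] = spec.to_state
            moved |= move
        follow[char] = new.astype(baseline[char].dtype)
    # keep MMSE consistent with the (possibly changed) cognition band
    changed = follow["cognition"] != baseline["cognition"]
    if changed.any():
        idx = np.flatnonzero(changed.to_numpy())
        cog = follow["cognition"].to_numpy()
        band_lo = np.array([27, 21, 10, 0])
        band_hi = np.array([30, 26, 20, 9])
        draws = rng.integers(band_lo[cog[idx]], band_hi[cog[idx]] + 1)
        mmse = follow["mmse"].to_numpy().copy()
        mmse[idx] = draws
        follow["mmse"] = mmse.astype(np.int16)
    follow["age_months"] = follow["age_months"] + 24
    return follow


def generate_study_extract(
    n: int,
    study_label: str,
    params: Optional[GroundTruthParams] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One study's two-wave panel: baseline columns, ``*_fu`` follow-up columns,
    ``followed_up`` attrition flag, study weights.

    Attrition is missing-at-random given age and sex; lost individuals keep
    baseline values in the ``*_fu`` columns but are flagged ``followed_up=0``
    and excluded from every fit.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    params = params or default_ground_truth()
    _validate_params(params)
    rng = np.random.default_rng(seed)
    baseline = generate_baseline(n, study_label, params, rng)
    follow = apply_truth_transitions(baseline, params, rng)

    eta = (
        logit(np.clip(params.attrition_rate, 1e-9, 1 - 1e-9))
        + params.attrition_age_slope * (baseline["age_months"].to_numpy() / 12.0 - 65.0)
        + params.attrition_female * baseline["sex"].to_numpy()
    )
    lost = rng.random(n) < expit(eta) if params.attrition_rate > 0 else np.zeros(n, bool)

    panel = baseline.copy()
    state_cols = [name for name, _ in STATE_COLUMNS if name not in ("id", "study", "weight")]
    for col in state_cols:
        panel[f"{col}_fu"] = follow[col]
    panel["followed_up"] = (~lost).astype(np.int8)
    return panel


# ---------------------------------------------------------------------------
# base-population construction: rake -> clone -> subsample
# ---------------------------------------------------------------------------
def default_target_margins(
    params: Optional[GroundTruthParams] = None, total: int = 3_000_000
) -> pd.DataFrame:
    """Age-band x sex population counts for a synthetic national population.

    Shares follow the generator's own age-weight anchors and female fraction,
    scaled to ``total`` people aged 35+.
    """
    params = params or default_ground_truth()
    ages = np.arange(35, MAX_BASELINE_AGE + 1)
    xs = [a for a, _ in params.age_anchors]
    ws = [w for _, w in params.age_anchors]
    weights = np.interp(ages, xs, ws)
    p_f = expit(
        logit(np.clip(expit(params.p_female["intercept"]), 1e-9, 1 - 1e-9))
        + params.p_female_old_age_slope * np.clip(ages - 65, 0, None)
    )
    df = pd.DataFrame(
        {
            "age_band": age_band_label(ages),
            "male": weights * (1 - p_f),
            "female": weights * p_f,
        }
    )
    margins = df.groupby("age_band", sort=False).sum().reset_index()
    margins = margins.melt(id_vars="age_band", var_name="sex", value_name="count")
    margins["count"] = margins["count"] / margins["count"].sum() * total
    margins["sex"] = margins["sex"].map({"male": 0, "female": 1}).astype(np.int8)
    return margins


def rake_weights(
    frame: pd.DataFrame,
    margins: Union[pd.DataFrame, Sequence[pd.DataFrame]],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Iterative proportional fitting of ``frame.weight`` to margin counts.

    Each margin table has a ``count`` column plus grouping columns (derived
    columns ``age_band`` are computed from ``age_months`` on the fly).  A
    single table is the common case (a full age-band x sex cross, where IPF
    converges in one sweep); several tables are cycled until every margin is
    matched within ``tol`` (relative) or ``max_iter`` sweeps.
    """
    margin_list = [margins] if isinstance(margins, pd.DataFrame) else list(margins)
    work = frame.copy()
    work["age_band"] = age_band_label(work["age_months"].to_numpy() / 12.0)
    w = work["weight"].to_numpy(float).copy()
    if (w < 0).any():
        raise RakingError("negative input weight")

    keys_list = []
    for m in margin_list:
        keys = [c for c in m.columns if c != "count"]
        if not keys:
            raise RakingError("margin table has no grouping columns")
        keys_list.append(keys)
        # coverage check: margin must exist for every populated cell
        cells = work.groupby(keys, sort=False).size().reset_index(name="_n")
        merged = cells.merge(m, on=keys, how="left")
        if merged["count"].isna().any():
            missing = merged.loc[merged["count"].isna(), keys].iloc[0].to_dict()
            raise RakingError(f"margins do not cover populated cell {missing}")
        # a positive margin with an empty sample cell can never be matched
        empty = m.merge(cells, on=keys, how="left")
        bad = (empty["_n"].isna()) & (empty["count"] > 0)
        if bad.any():
            cell = empty.loc[bad, keys].iloc[0].to_dict()
            raise RakingError(f"margin cell {cell} has target > 0 but no sample rows")

    for _ in range(max_iter):
        max_rel_err = 0.0
        for m, keys in zip(margin_list, keys_list):
            work["_w"] = w
            current = work.groupby(keys, sort=False)["_w"].sum().reset_index()
            adj = m.merge(current, on=keys, how="inner")
            adj["_factor"] = adj["count"] / adj["_w"]
            factors = work[keys].merge(adj[keys + ["_factor"]], on=keys, how="left")["_factor"]
            w = w * factors.fillna(1.0).to_numpy()
            rel = np.abs(adj["_w"] * adj["_factor"] - adj["count"]) / np.maximum(adj["count"], 1e-300)
            max_rel_err = max(max_rel_err, float(rel.max()))
        # check all margins simultaneously
        ok = True
        work["_w"] = w
        for m, keys in zip(margin_list, keys_list):
            current = work.groupby(keys, sort=False)["_w"].sum().reset_index()
            adj = m.merge(current, on=keys, how="inner")
            rel = np.abs(adj["_w"] - adj["count"]) / np.maximum(adj["count"], 1e-300)
            if float(rel.max()) > tol:
                ok = False
        if ok:
            return w
    raise RakingError(f"IPF did not converge within {max_iter} iterations")


def build_base_population(
    extracts: Sequence[pd.DataFrame],
    target_margins: pd.DataFrame,
    sampling_fraction: float = 0.01,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Pool study baselines, rake to national margins, clone, subsample.

    Weights are raked to the age-band x sex ``target_margins``, each row is
    cloned ``round(weight)`` times (round-half-to-even) so that everyone
    carries unit weight, and a simple random sample of
    ``round(sampling_fraction * clones)`` rows is drawn.  Returned weights
    are all exactly 1.
    """
    if not extracts:
        raise ConfigurationError("no study extracts supplied")
    if not 0 < sampling_fraction <= 1:
        raise ConfigurationError("sampling_fraction must lie in (0, 1]")
    base_cols = [name for name, _ in STATE_COLUMNS]
    pooled = pd.concat([e[base_cols] for e in extracts], ignore_index=True)
    rng = np.random.default_rng(seed)

    w = rake_weights(pooled, target_margins)
    clones_per_row = np.rint(w).astype(np.int64)
    total_clones = int(clones_per_row.sum())
    if total_clones == 0:
        raise RakingError("all raked weights round to zero")
    n_sample = int(round(sampling_fraction * total_clones))
    n_sample = max(n_sample, 1)
    clone_index = np.repeat(np.arange(len(pooled)), clones_per_row)
    chosen = rng.choice(clone_index, size=n_sample, replace=False)
    sample = pooled.iloc[chosen].reset_index(drop=True)
    sample["weight"] = 1.0
    sample["id"] = np.arange(len(sample), dtype=np.int64)
    return validate_population(sample, context="base population")


# ---------------------------------------------------------------------------
# dementia allocation table
# ---------------------------------------------------------------------------
DEMENTIA_AGE_GROUPS = ("35-64", "65-74", "75-84", "85+")


def generate_dementia_table(params: Optional[GroundTruthParams] = None) -> pd.DataFrame:
    """Allocation probabilities by age group x cognition category x residence.

    Probabilities rise with age group and with cognitive impairment severity,
    and are shifted up (on the logit scale) in care homes.
    """
    params = params or default_ground_truth()
    rows = []
    base = np.asarray(params.dementia_base, dtype=float)
    if np.any((base < 0) | (base > 1)):
        raise ConfigurationError("dementia base probabilities must lie in [0, 1]")
    for group in DEMENTIA_AGE_GROUPS:
        mult = params.dementia_age_multiplier[group]
        for cognition in range(4):
            p_community = float(np.clip(base[cognition] * mult, 0.0, 0.995))
            for residence in (0, 1):
                p = p_community
                if residence == 1 and 0 < p < 1:
                    p = float(expit(logit(p) + params.dementia_care_home_logit_shift))
                rows.append(
                    {
                        "age_group": group,
                        "cognition": cognition,
                        "residence": residence,
                        "probability": p,
                    }
                )
    table = pd.DataFrame(rows)
    if ((table["probability"] < 0) | (table["probability"] > 1)).any():
        raise ConfigurationError("dementia probabilities must lie in [0, 1]")
    return table


def dementia_age_group(age_years) -> np.ndarray:
    age = np.asarray(age_years)
    return np.select(
        [age < 65, age < 75, age < 85], ["35-64", "65-74", "75-84"], default="85+"
    ).astype(object)
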