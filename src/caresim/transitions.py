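"""Per-characteristic transition models and probability rescaling.

Every stochastic characteristic (everything except age, sex, education and
occupation) gets one weighted logistic regression per allowed state change,
fitted to baseline -> 2-year follow-up state changes in a pooled panel.
Ordered characteristics move one severity step at a time: each model covers a
single adjacent transition ("up" towards worse severity, "down" = recovery to
the next less severe category).  Dementia is never a covariate — it is
allocated after the simulation, outside the monthly loop.

Fitted 2-year probabilities are rescaled to the engine's monthly step under a
constant-hazard assumption: ``p_month = 1 - (1 - p_biennial)**(1/24)``, and
annual survival probabilities become monthly as ``s**(1/12)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .exceptions import EstimationError, InputDomainError
from .population import DISEASES, design_matrix

__all__ = [
    "TransitionSpec",
    "TransitionModel",
    "ModelSet",
    "TRANSITIONS",
    "biennial_to_monthly",
    "annual_survival_to_monthly",
    "fit_transition_model",
    "fit_all_transitions",
    "predict_transition",
]

MONTHS_PER_PANEL_WAVE = 24


# ---------------------------------------------------------------------------
# probability rescaling
# ---------------------------------------------------------------------------
def biennial_to_monthly(p_biennial: float) -> float:
    """Rescale a 2-year transition probability to one month.

    Uses the complement-compounding (constant hazard) form
    ``1 - (1 - p)**(1/24)``, so that 24 independent monthly draws reproduce
    the biennial probability exactly.
    """
    p = np.asarray(p_biennial, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InputDomainError(f"biennial probability outside [0, 1]: {p_biennial!r}")
    out = 1.0 - (1.0 - p) ** (1.0 / MONTHS_PER_PANEL_WAVE)
    return float(out) if np.isscalar(p_biennial) else out


def annual_survival_to_monthly(s_annual: float) -> float:
    """Monthly survival probability ``s**(1/12)`` from annual survival."""
    s = np.asarray(s_annual, dtype=float)
    if np.any((s <= 0) | (s > 1)) or np.any(np.isnan(s)):
        raise InputDomainError(f"annual survival outside (0, 1]: {s_annual!r}")
    out = s ** (1.0 / 12.0)
    return float(out) if np.isscalar(s_annual) else out


# ---------------------------------------------------------------------------
# transition registry
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class TransitionSpec:
    """One allowed state change of one characteristic."""

    characteristic: str
    from_state: int
    to_state: int
    direction: str  # "incidence" (worse / onset) or "recovery"
    covariates: tuple[str, ...]

    @property
    def key(self) -> str:
        return f"{self.characteristic}:{self.from_state}>{self.to_state}"


_BASE = ("intercept", "age_c", "age_c2", "female")
_DEP_EXTRA = ("n_diseases", "cognitive_impairment", "low_education")
_CARDIO_EXTRA = ("current_smoker", "obese", "low_activity")


def _spec(char, a, b, direction, extra=()):
    return TransitionSpec(char, a, b, direction, _BASE + tuple(extra))


def default_transitions() -> tuple[TransitionSpec, ...]:
    """The registry of modelled state changes.

    Diseases are chronic (onset only) except depression, which also recovers.
    Ordered characteristics step one level at a time; recovery models exist
    for low/medium/high physical dependency, mild and moderate cognitive
    impairment, depression, and visual and hearing impairment.  Severe
    cognitive impairment does not recover.
    """
    specs: list[TransitionSpec] = []
    # health behaviours
    specs += [
        _spec("smoking", 2, 1, "recovery"),            # quitting
        _spec("smoking", 1, 2, "incidence"),           # relapse
        _spec("bmi_class", 0, 1, "incidence", ("low_activity",)),
        _spec("bmi_class", 1, 2, "incidence", ("low_activity",)),
        _spec("bmi_class", 1, 0, "recovery"),
        _spec("bmi_class", 2, 1, "recovery"),
        _spec("physical_activity", 2, 1, "incidence"),  # towards less active
        _spec("physical_activity", 1, 0, "incidence"),
        _spec("physical_activity", 1, 2, "recovery"),
        _spec("physical_activity", 0, 1, "recovery"),
    ]
    # chronic diseases: onset
    for d in DISEASES:
        extra = _CARDIO_EXTRA if d in ("chd", "stroke", "hypertension", "diabetes") else ()
        if d == "respiratory":
            extra = ("current_smoker",)
        specs.append(_spec(d, 0, 1, "incidence", extra))
    specs.append(_spec("depression", 1, 0, "recovery"))
    # sensory impairments
    for s in ("vision", "hearing"):
        specs += [
            _spec(s, 0, 1, "incidence"),
            _spec(s, 1, 2, "incidence"),
            _spec(s, 1, 0, "recovery"),
            _spec(s, 2, 1, "recovery"),
        ]
    # cognition (no recovery from severe)
    specs += [
        _spec("cognition", 0, 1, "incidence"),
        _spec("cognition", 1, 2, "incidence"),
        _spec("cognition", 2, 3, "incidence"),
        _spec("cognition", 1, 0, "recovery"),
        _spec("cognition", 2, 1, "recovery"),
    ]
    # physical dependency (cognition-free); risk-factor covariates included
    for a, b in ((0, 1), (1, 2), (2, 3)):
        specs.append(_spec("phys_dep", a, b, "incidence", _DEP_EXTRA))
    for a, b in ((1, 0), (2, 1), (3, 2)):
        specs.append(_spec("phys_dep", a, b, "recovery", _DEP_EXTRA))
    return tuple(specs)


TRANSITIONS: tuple[TransitionSpec, ...] = default_transitions()

#: Characteristics the engine updates stochastically, in default update order:
#: behaviours -> diseases -> sensory -> cognition -> physical dependency.
STOCHASTIC_CHARACTERISTICS: tuple[str, ...] = (
    "smoking",
    "bmi_class",
    "physical_activity",
    *DISEASES,
    "vision",
    "hearing",
    "cognition",
    "phys_dep",
)


# ---------------------------------------------------------------------------
# fitted model container
# ---------------------------------------------------------------------------
@dataclass
class TransitionModel:
    """Frozen logit coefficients for one characteristic's state change."""

    characteristic: str
    from_state: int
    to_state: int
    direction: str
    covariates: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)
    n: int = 0
    events: int = 0

    def __post_init__(self) -> None:
        if "dementia" in self.covariates:
            raise EstimationError(
                f"{self.characteristic}: dementia may not be a transition covariate"
            )
        missing = set(self.covariates) - set(self.coefficients)
        if missing:
            raise EstimationError(
                f"{self.characteristic}: coefficients missing for {sorted(missing)}"
            )

    @property
    def key(self) -> str:
        return f"{self.characteristic}:{self.from_state}>{self.to_state}"

    def linear_predictor(self, frame) -> np.ndarray:
        X = design_matrix(self.covariates, frame)
        beta = np.array([self.coefficients[c] for c in self.covariates])
        return X @ beta

    def biennial_probability(self, frame) -> np.ndarray:
        return expit(self.linear_predictor(frame))

    def monthly_probability(self, frame) -> np.ndarray:
        return biennial_to_monthly(self.biennial_probability(frame))

    def to_dict(self) -> dict:
        return {
            "characteristic": self.characteristic,
            "from_state": self.from_state,
            "to_state": self.to_state,
            "direction": self.direction,
            "covariates": list(self.covariates),
            "coefficients": self.coefficients,
            "standard_errors": self.standard_errors,
            "n": self.n,
            "events": self.events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionModel":
        return cls(
            characteristic=d["characteristic"],
            from_state=int(d["from_state"]),
            to_state=int(d["to_state"]),
            direction=d["direction"],
            covariates=tuple(d["covariates"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            standard_errors={k: float(v) for k, v in d.get("standard_errors", {}).items()},
            n=int(d.get("n", 0)),
            events=int(d.get("events", 0)),
        )


class ModelSet:
    """All fitted transition models, keyed by ``char:from>to``."""

    def __init__(self, models: Sequence[TransitionModel] = ()):
        self._models: dict[str, TransitionModel] = {}
        for m in models:
            self.add(m)

    def add(self, model: TransitionModel) -> None:
        self._models[model.key] = model

    def __len__(self) -> int:
        return len(self._models)

    def __iter__(self):
        return iter(self._models.values())

    def __contains__(self, key: str) -> bool:
        return key in self._models

    def get(self, characteristic: str, from_state: int, to_state: int) -> Optional[TransitionModel]:
        return self._models.get(f"{characteristic}:{from_state}>{to_state}")

    def models_from(self, characteristic: str, from_state: int) -> list[TransitionModel]:
        return [
            m
            for m in self._models.values()
            if m.characteristic == characteristic and m.from_state == from_state
        ]

    def save(self, path: Union[str, Path], metadata: Optional[dict] = None) -> None:
        doc = {
            "metadata": metadata or {},
            "models": [m.to_dict() for m in sorted(self._models.values(), key=lambda m: m.key)],
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path: Union[str, Path]) -> "ModelSet":
        doc = json.loads(Path(path).read_text())
        return cls([TransitionModel.from_dict(d) for d in doc["models"]])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------
def _at_risk(panel: pd.DataFrame, spec: TransitionSpec) -> pd.DataFrame:
    fu = f"{spec.characteristic}_fu"
    if fu not in panel.columns:
        raise EstimationError(f"{spec.characteristic}: panel lacks follow-up column {fu!r}")
    mask = (panel["followed_up"] == 1) & (panel[spec.characteristic] == spec.from_state)
    return panel.loc[mask]


def fit_transition_model(
    panel: pd.DataFrame,
    spec: TransitionSpec,
    min_at_risk: int = 50,
) -> TransitionModel:
    """Weighted logistic regression of one state change on baseline covariates.

    ``panel`` holds baseline columns, follow-up columns suffixed ``_fu``, a
    ``followed_up`` 0/1 flag (attrition) and a ``weight`` column of study
    weights.  Weights are normalised to mean one, which makes the fit (both
    coefficients and standard errors) invariant to uniform rescaling.

    Raises
    ------
    EstimationError
        Too few at-risk individuals, zero or saturated events, or failure to
        converge (e.g. complete separation), always naming the characteristic.
    """
    at_risk = _at_risk(panel, spec)
    if len(at_risk) < min_at_risk:
        raise EstimationError(
            f"{spec.characteristic} {spec.from_state}>{spec.to_state}: "
            f"only {len(at_risk)} at-risk individuals (need {min_at_risk})"
        )
    y = (at_risk[f"{spec.characteristic}_fu"] == spec.to_state).to_numpy(int)
    if y.sum() == 0:
        raise EstimationError(
            f"{spec.characteristic} {spec.from_state}>{spec.to_state}: zero events"
        )
    if y.sum() == len(y):
        raise EstimationError(
            f"{spec.characteristic} {spec.from_state}>{spec.to_state}: every individual transitions"
        )
    X = design_matrix(spec.covariates, at_risk)
    keep = list(spec.covariates)
    constant = [
        name
        for j, name in enumerate(spec.covariates)
        if name != "intercept" and np.ptp(X[:, j]) == 0
    ]
    if constant:
        warnings.warn(
            f"{spec.characteristic}: dropping constant covariate(s) {constant}",
            stacklevel=2,
        )
        keep = [c for c in keep if c not in constant]
        X = design_matrix(keep, at_risk)
    w = at_risk["weight"].to_numpy(float)
    if w.min() < 0:
        raise EstimationError(f"{spec.characteristic}: negative study weight")
    w = w / w.mean()
    try:
        with warnings.catch_warnings():
            # benign overflow inside IRLS is routine; separation is caught below
            warnings.simplefilter("ignore", category=RuntimeWarning)
            # survey-style weights: coefficients from the weighted score,
            # standard errors from the robust sandwich (per-observation
            # scores carry the weight, as for probability weights)
            result = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w).fit(
                cov_type="HC1"
            )
    except Exception as exc:  # PerfectSeparation, singular design ...
        raise EstimationError(
            f"{spec.characteristic} {spec.from_state}>{spec.to_state}: GLM failed ({exc})"
        ) from exc
    if (
        not np.all(np.isfinite(result.params))
        or not np.all(np.isfinite(result.bse))
        or np.abs(result.params).max() > 50
    ):
        raise EstimationError(
            f"{spec.characteristic} {spec.from_state}>{spec.to_state}: degenerate estimates "
            "(possible complete separation)"
        )
    return TransitionModel(
        characteristic=spec.characteristic,
        from_state=spec.from_state,
        to_state=spec.to_state,
        direction=spec.direction,
        covariates=tuple(keep),
        coefficients=dict(zip(keep, map(float, result.params))),
        standard_errors=dict(zip(keep, map(float, result.bse))),
        n=int(len(y)),
        events=int(y.sum()),
    )


def fit_all_transitions(
    panel: pd.DataFrame,
    specs: Sequence[TransitionSpec] = TRANSITIONS,
    min_at_risk: int = 50,
    skip_sparse: bool = True,
) -> ModelSet:
    """Fit every registered transition on the pooled panel.

    With ``skip_sparse`` (default), transitions that cannot be estimated from
    the panel (too few at risk or zero events — common for rare recovery
    steps at modest panel sizes) are omitted from the returned set rather
    than aborting the whole fit; the engine treats an absent model as a
    structural zero.  Genuine numerical failures still raise.
    """
    models = ModelSet()
    skipped: list[str] = []
    for spec in specs:
        try:
            models.add(fit_transition_model(panel, spec, min_at_risk=min_at_risk))
        except EstimationError as exc:
            msg = str(exc)
            sparse = (
                "at-risk individuals" in msg
                or "zero events" in msg
                or "degenerate estimates" in msg
            )
            if skip_sparse and sparse:
                skipped.append(spec.key)
                continue
            raise
    if skipped:
        warnings.warn(f"transitions skipped for sparsity: {', '.join(skipped)}", stacklevel=2)
    return models


def predict_transition(model: TransitionModel, state) -> float:
    """Monthly transition probability for one individual (or a frame of them).

    Applies the inverse logit to the linear predictor on the 2-year scale,
    then rescales to a month.  Missing covariates raise
    :class:`CovariateError` naming the covariate.
    """
    frame = state.to_frame() if hasattr(state, "to_frame") and not isinstance(state, pd.DataFrame) else state
    p = model.monthly_probability(frame)
    return float(p[0]) if np.size(p) == 1 else p
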