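"""Population state schema shared by the generator, fitter and engine.

A population is a :class:`pandas.DataFrame` with one row per individual and
integer-coded characteristics (codebook below).  Integer codes keep the
monthly engine vectorisable and the CSV round trip exact; helper functions
translate to readable labels at the I/O boundary.

Codebook
--------
========================  =====================================================
column                    codes
========================  =====================================================
sex                       0 male, 1 female
education                 0 low, 1 mid, 2 high (ordered)
occupation                0 manual, 1 non-manual
smoking                   0 never, 1 former, 2 current
bmi_class                 0 normal, 1 overweight, 2 obese (ordered)
physical_activity         0 low, 1 moderate, 2 high (ordered)
chd ... depression        0 absent, 1 present (eight chronic diseases)
vision, hearing           0 none, 1 some, 2 severe impairment (ordered)
mmse                      integer score 0-30
cognition                 0 normal, 1 mild, 2 moderate, 3 severe (from MMSE)
phys_dep                  0 independent, 1 low, 2 medium, 3 high (cognition-free)
residence                 0 community, 1 care home
dementia                  0/1 (assigned only by post-simulation allocation)
alive                     0/1
========================  =====================================================

``age_months`` is an integer (>= 420, i.e. age 35); ``weight`` a non-negative
sampling weight; ``id`` an opaque integer; ``study`` a string label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, CovariateError
from .interval_of_need import CognitionCategory, IntervalOfNeed

__all__ = [
    "DISEASES",
    "STATE_COLUMNS",
    "LABELS",
    "IndividualState",
    "compute_covariate",
    "design_matrix",
    "validate_population",
    "cognition_from_mmse",
]

#: The eight self-report chronic diseases tracked per individual.
DISEASES = (
    "chd",
    "stroke",
    "hypertension",
    "diabetes",
    "arthritis",
    "cancer",
    "respiratory",
    "depression",
)

#: Ordered/categorical characteristic -> number of levels.
CATEGORICAL_LEVELS: dict[str, int] = {
    "sex": 2,
    "education": 3,
    "occupation": 2,
    "smoking": 3,
    "bmi_class": 3,
    "physical_activity": 3,
    "vision": 3,
    "hearing": 3,
    "cognition": 4,
    "phys_dep": 4,
    "residence": 2,
}

STATE_COLUMNS = (
    ("id", "int64"),
    ("study", "object"),
    ("sex", "int8"),
    ("age_months", "int32"),
    ("education", "int8"),
    ("occupation", "int8"),
    ("smoking", "int8"),
    ("bmi_class", "int8"),
    ("physical_activity", "int8"),
    *((d, "int8") for d in DISEASES),
    ("vision", "int8"),
    ("hearing", "int8"),
    ("mmse", "int16"),
    ("cognition", "int8"),
    ("phys_dep", "int8"),
    ("residence", "int8"),
    ("dementia", "int8"),
    ("alive", "int8"),
    ("weight", "float64"),
)

LABELS: dict[str, tuple[str, ...]] = {
    "sex": ("male", "female"),
    "education": ("low", "mid", "high"),
    "occupation": ("manual", "non-manual"),
    "smoking": ("never", "former", "current"),
    "bmi_class": ("normal", "overweight", "obese"),
    "physical_activity": ("low", "moderate", "high"),
    "vision": ("none", "some", "severe"),
    "hearing": ("none", "some", "severe"),
    "cognition": ("normal", "mild", "moderate", "severe"),
    "phys_dep": ("independent", "low", "medium", "high"),
    "residence": ("community", "care_home"),
}

MIN_AGE_MONTHS = 35 * 12


def cognition_from_mmse(mmse) -> np.ndarray:
    """Vectorised MMSE -> cognition code (0 normal ... 3 severe)."""
    m = np.asarray(mmse)
    return np.select([m <= 9, m <= 20, m <= 26], [3, 2, 1], default=0).astype(np.int8)


@dataclass
class IndividualState:
    """One simulated person; the scalar view of a population row."""

    id: int
    sex: int
    age_months: int
    education: int
    occupation: int
    smoking: int
    bmi_class: int
    physical_activity: int
    chd: int
    stroke: int
    hypertension: int
    diabetes: int
    arthritis: int
    cancer: int
    respiratory: int
    depression: int
    vision: int
    hearing: int
    mmse: int
    cognition: int
    phys_dep: int
    residence: int
    dementia: int = 0
    alive: int = 1
    weight: float = 1.0
    study: str = ""

    def interval_of_need(self) -> IntervalOfNeed:
        """Combined dependency: physical level floored by severe cognition."""
        floor = 3 if self.cognition == CognitionCategory.SEVERE else 0
        return IntervalOfNeed(max(self.phys_dep, floor))

    def to_frame(self) -> pd.DataFrame:
        row = {name: getattr(self, name) for name, _ in STATE_COLUMNS}
        return pd.DataFrame([row]).astype(dict(STATE_COLUMNS))

    @classmethod
    def from_row(cls, row: Mapping) -> "IndividualState":
        return cls(**{name: row[name] for name, _ in STATE_COLUMNS})


# ---------------------------------------------------------------------------
# covariate registry
# ---------------------------------------------------------------------------
def _age_years(frame) -> np.ndarray:
    return np.asarray(frame["age_months"], dtype=float) / 12.0


def _n_diseases(frame) -> np.ndarray:
    return sum(np.asarray(frame[d], dtype=float) for d in DISEASES)


#: name -> function(frame-like) -> float array.  ``frame`` may be a DataFrame
#: or any mapping of column name to array.
COVARIATES = {
    "intercept": lambda f: np.ones_like(_age_years(f)),
    # age in years centred at 65; quadratic term scaled by /100 so that
    # coefficients on both terms are O(1)
    "age_c": lambda f: _age_years(f) - 65.0,
    "age_c2": lambda f: (_age_years(f) - 65.0) ** 2 / 100.0,
    "female": lambda f: np.asarray(f["sex"], dtype=float),
    "n_diseases": _n_diseases,
    "cognitive_impairment": lambda f: (np.asarray(f["cognition"]) >= 1).astype(float),
    "current_smoker": lambda f: (np.asarray(f["smoking"]) == 2).astype(float),
    "former_smoker": lambda f: (np.asarray(f["smoking"]) == 1).astype(float),
    "obese": lambda f: (np.asarray(f["bmi_class"]) == 2).astype(float),
    "overweight": lambda f: (np.asarray(f["bmi_class"]) == 1).astype(float),
    "low_activity": lambda f: (np.asarray(f["physical_activity"]) == 0).astype(float),
    "care_home": lambda f: np.asarray(f["residence"], dtype=float),
    "low_education": lambda f: (np.asarray(f["education"]) == 0).astype(float),
    **{d: (lambda f, _d=d: np.asarray(f[_d], dtype=float)) for d in DISEASES},
}


def compute_covariate(name: str, frame) -> np.ndarray:
    """Evaluate one named covariate; unknown names raise :class:`CovariateError`."""
    try:
        func = COVARIATES[name]
    except KeyError:
        raise CovariateError(f"unknown covariate {name!r}") from None
    try:
        return func(frame)
    except KeyError as exc:
        raise CovariateError(
            f"covariate {name!r} needs column {exc.args[0]!r}, absent from state"
        ) from None


def design_matrix(names, frame) -> np.ndarray:
    """Stack covariates column-wise into an (n, k) design matrix."""
    cols = [compute_covariate(name, frame) for name in names]
    return np.column_stack(cols) if cols else np.empty((len(frame), 0))


def validate_population(frame: pd.DataFrame, context: str = "population") -> pd.DataFrame:
    """Check schema, codes and invariants; return the frame with canonical dtypes.

    Raises :class:`ConfigurationError` naming the offending column (and the
    first offending row) on any violation.
    """
    for name, dtype in STATE_COLUMNS:
        if name not in frame.columns:
            raise ConfigurationError(f"{context}: missing column {name!r}")
        if name == "study":
            continue
        col = frame[name]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ConfigurationError(
                f"{context}: non-numeric value {col[row]!r} in column {name!r}, row {row}"
            )
        frame = frame.assign(**{name: numeric.astype(dtype)})
    for name, n_levels in CATEGORICAL_LEVELS.items():
        col = frame[name]
        if ((col < 0) | (col >= n_levels)).any():
            raise ConfigurationError(f"{context}: column {name!r} outside codes 0..{n_levels-1}")
    for name in (*DISEASES, "dementia", "alive"):
        if (~frame[name].isin((0, 1))).any():
            raise ConfigurationError(f"{context}: column {name!r} must be 0/1")
    if ((frame["mmse"] < 0) | (frame["mmse"] > 30)).any():
        raise ConfigurationError(f"{context}: mmse outside 0..30")
    if (frame["age_months"] < MIN_AGE_MONTHS).any():
        raise ConfigurationError(f"{context}: age below {MIN_AGE_MONTHS} months")
    if (frame["weight"] < 0).any():
        raise ConfigurationError(f"{context}: negative sampling weight")
    return frame[[name for name, _ in STATE_COLUMNS]]
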