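"""Shared fixtures: small synthetic datasets reused across test modules."""

import warnings

import pandas as pd
import pytest

import caresim as cs


@pytest.fixture(scope="session")
def params_small():
    p = cs.default_ground_truth()
    p.studies["household-panel"]["n"] = 4000
    p.studies["ageing-50plus"]["n"] = 1300
    p.studies["ageing-65plus"]["n"] = 800
    return p


@pytest.fixture(scope="session")
def extracts_small(params_small):
    return [
        cs.generate_study_extract(params_small.studies[label]["n"], label, params_small, seed=100 + i)
        for i, label in enumerate(sorted(params_small.studies))
    ]


@pytest.fixture(scope="session")
def panel_small(extracts_small):
    return pd.concat(extracts_small, ignore_index=True)


@pytest.fixture(scope="session")
def fitted_models(panel_small):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cs.fit_all_transitions(panel_small)


@pytest.fixture(scope="session")
def truth_models(params_small):
    return cs.truth_modelset(params_small)


@pytest.fixture(scope="session")
def lifetable():
    return cs.generate_lifetable()


@pytest.fixture(scope="session")
def dementia_table(params_small):
    return cs.generate_dementia_table(params_small)


@pytest.fixture(scope="session")
def base_small(extracts_small, params_small):
    margins = cs.default_target_margins(params_small, total=200_000)
    return cs.build_base_population(extracts_small, margins, sampling_fraction=0.02, seed=11)


@pytest.fixture(scope="session")
def quiet_modelset(truth_models):
    """Truth models with every transition switched structurally off."""
    off = []
    for m in truth_models:
        coefs = {name: 0.0 for name in m.covariates}
        coefs["intercept"] = -50.0
        off.append(
            cs.TransitionModel(
                characteristic=m.characteristic,
                from_state=m.from_state,
                to_state=m.to_state,
                direction=m.direction,
                covariates=m.covariates,
                coefficients=coefs,
            )
        )
    return cs.ModelSet(off)


@pytest.fixture(scope="session")
def immortal_lifetable():
    frame = cs.generate_lifetable().table[["sex", "age", "survival"]].copy()
    frame["survival"] = 1.0
    return cs.LifeTable(frame)
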