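"""Shared fixtures: small simulated cohorts and one fitted joint model.

Session scope keeps the expensive objects (joint fits) shared across test
modules; all randomness is seeded so the suite is reproducible.
"""

import numpy as np
import pandas as pd
import pytest

from bnpjm import JointConfig, fit_joint, preprocess
from bnpjm.data_model import make_cohort
from bnpjm.simulate import TRUTH_SCALING, default_truth, simulate_cohort


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def cohort20(truth):
    """20-subject fixture for likelihood-oracle comparisons."""
    return preprocess(simulate_cohort(truth, 20, seed=7),
                      constants=TRUTH_SCALING)


@pytest.fixture(scope="session")
def cohort150(truth):
    """Mid-size fitting fixture."""
    return preprocess(simulate_cohort(truth, 150, seed=3),
                      constants=TRUTH_SCALING)


@pytest.fixture(scope="session")
def fit_death150(cohort150):
    """Joint model for death on the mid-size fixture, with vcov."""
    fit = fit_joint(cohort150, "death",
                    JointConfig(nodes=7, quadrature="pseudo-adaptive"))
    assert fit.converged
    return fit


def toy_tables():
    """Two hand-written subjects with three visits each."""
    long_df = pd.DataFrame({
        "subject_id": ["A", "A", "A", "B", "B", "B"],
        "time": [0.0, 0.5, 1.0, 0.0, 0.6, 1.1],
        "value": [64.0, 70.0, 72.0, 381.0, 287.0, 1068.0],
    })
    surv_df = pd.DataFrame({
        "subject_id": ["A", "B"],
        "obs_time": [2.0, 1.5],
        "status_death": [0, 1],
        "status_intervention": [0, 0],
        "ava": [0.96, 0.61],
        "age": [72.0, 79.0],
        "symptoms": [0, 1],
        "male": [1, 1],
        "lvef": [61.0, 61.0],
        "creatinine": [92.0, 92.0],
    })
    return long_df, surv_df


@pytest.fixture()
def toy_cohort():
    return make_cohort(*toy_tables())


@pytest.fixture()
def toy_csvs(tmp_path):
    long_df, surv_df = toy_tables()
    lp, sp = tmp_path / "long.csv", tmp_path / "surv.csv"
    long_df.to_csv(lp, index=False)
    surv_df.to_csv(sp, index=False)
    return lp, sp
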