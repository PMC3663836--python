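import dataclasses

import numpy as np
import pandas as pd
import pytest

import mirgist as mg


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, shared across tests (seed fixed)."""
    return mg.simulate_cohort(mg.SimConfig(seed=42))


@pytest.fixture(scope="session")
def expression(cohort):
    return mg.preprocess_pipeline(cohort.ct)


@pytest.fixture(scope="session")
def case_fixture():
    return mg.load_case_fixture()


@pytest.fixture()
def small_ct_matrix():
    """A hand-sized 4 x 3 raw Ct matrix with one missing cell."""
    values = pd.DataFrame(
        {
            "S1": [20.0, 30.0, 25.0, 34.0],
            "S2": [21.0, 31.0, np.nan, 36.0],
            "S3": [19.0, 29.0, 27.0, 33.0],
        },
        index=["miR-a", "miR-b", "miR-c", "miR-d"],
    )
    return mg.CtMatrix(values, stage="raw")


def subset_expression(expr, samples):
    return dataclasses.replace(expr, values=expr.values[list(samples)])
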