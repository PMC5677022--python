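import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile(
    "mirgi",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
hypothesis_settings.load_profile("mirgi")

from mirgi import SignatureSpec, simulate_cohort
from mirgi.data_io import ExpressionMatrix
from mirgi.instability import mutation_counts


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Package warnings are assertions of behaviour elsewhere; keep runs quiet."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@pytest.fixture(scope="session")
def default_cohort():
    """One default-parameter simulated cohort shared across tests."""
    return simulate_cohort(seed=0)


@pytest.fixture(scope="session")
def default_burden(default_cohort):
    return mutation_counts(default_cohort.bundle.mutations, default_cohort.bundle.sample_ids)


@pytest.fixture(scope="session")
def planted_signature(default_cohort):
    p = default_cohort.planted
    return SignatureSpec(
        tuple(p.loc[p["sign"] > 0, "mirna_id"]),
        tuple(p.loc[p["sign"] < 0, "mirna_id"]),
        name="planted",
    )


def make_expression(values, mirnas=None, samples=None) -> ExpressionMatrix:
    arr = np.asarray(values, dtype=float)
    mirnas = mirnas or [f"mir-{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=mirnas, columns=samples))
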