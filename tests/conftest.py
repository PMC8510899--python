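import numpy as np
import pytest

from osteocea import (
    OFF_TREATMENT,
    TREATMENT,
    default_parameters,
    evaluate,
    run_cohort,
)


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_summary(params):
    """Base-case two-arm evaluation, shared across tests (deterministic)."""
    return evaluate(params)


@pytest.fixture(scope="session")
def base_traces(params):
    return {
        TREATMENT: run_cohort(params, TREATMENT),
        OFF_TREATMENT: run_cohort(params, OFF_TREATMENT),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
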