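import pytest

from fruqcea import load_parameters, run_traces

#: suite-wide seed for every stochastic test
SEED = 0


@pytest.fixture(scope="session")
def params():
    """Packaged default registry with the frozen calibration."""
    return load_parameters()


@pytest.fixture(scope="session")
def traces(params):
    """Cohort traces under the frozen calibration (reused across tests)."""
    return run_traces(params)
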