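import numpy as np
import pytest

from svrlsm.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 37-participant synthetic cohort, shared across tests."""
    return generate_cohort(SyntheticConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
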