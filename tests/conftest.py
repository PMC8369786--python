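import numpy as np
import pytest

from ccar.synthetic import generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort, shared across tests (seed fixed)."""
    return generate_cohort(seed=20210817)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
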