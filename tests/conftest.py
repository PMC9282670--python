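import numpy as np
import pytest

from sccat import SimulationConfig, generate_cohort, packaged_bank


@pytest.fixture(scope="session")
def bank():
    return packaged_bank()


@pytest.fixture(scope="session")
def default_cohort(bank):
    """The study-condition cohort: n=1000, theta~N(0,1), cutoff 0.88."""
    return generate_cohort(bank, SimulationConfig(n=1000, seed=7))


@pytest.fixture(scope="session")
def small_cohort(bank):
    return generate_cohort(bank, SimulationConfig(n=200, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
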