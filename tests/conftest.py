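import numpy as np
import pytest

from riokit import synth


@pytest.fixture(scope="session")
def amplicons():
    return synth.default_amplicons()


@pytest.fixture(scope="session")
def brca1(amplicons):
    return amplicons["BRCA1"]


@pytest.fixture(scope="session")
def rad51c(amplicons):
    return amplicons["RAD51C"]


@pytest.fixture(scope="session")
def small_cohort():
    """20-patient cohort shared by pipeline-level tests."""
    return synth.generate_cohort(synth.CohortConfig(n_patients=20, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
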