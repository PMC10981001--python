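import numpy as np
import pytest

from ssia_dosekit.cohort_io import table3_fixture
from ssia_dosekit.dosimetry import load_nuclides


@pytest.fixture(scope="session")
def fixture_cohort():
    return table3_fixture()


@pytest.fixture(scope="session")
def nuclides():
    return load_nuclides()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240322)
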