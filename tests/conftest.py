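import numpy as np
import pytest

from qamskit.fixtures import fixture_group_labels, fixture_table3


@pytest.fixture(scope="session")
def table3():
    """(ESM, QAMS) content matrices of the embedded 23-batch panel."""
    return fixture_table3()


@pytest.fixture(scope="session")
def qams_matrix(table3):
    return table3[1]


@pytest.fixture(scope="session")
def esm_matrix(table3):
    return table3[0]


@pytest.fixture(scope="session")
def group_labels():
    return fixture_group_labels()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
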