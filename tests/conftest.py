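import pytest

from chorotypes import load_fixture
from chorotypes.pipeline import analyse_mode


@pytest.fixture(scope="session")
def pa():
    return load_fixture("venezuela_marsupials_pa")


@pytest.fixture(scope="session")
def env():
    return load_fixture("venezuela_env")


@pytest.fixture(scope="session")
def q_result(pa):
    """Full Q-mode classification of the study fixture at default settings."""
    return analyse_mode(pa, "Q")


@pytest.fixture(scope="session")
def r_result(pa):
    """Full R-mode classification of the study fixture at default settings."""
    return analyse_mode(pa, "R")
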