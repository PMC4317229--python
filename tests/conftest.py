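import pytest

from tmddpk.params import (
    human_parameters,
    monkey_iiv,
    monkey_parameters,
    monkey_residual_error,
)


@pytest.fixture(scope="session")
def monkey():
    """Typical cynomolgus QE-TMDD parameter set."""
    return monkey_parameters()


@pytest.fixture(scope="session")
def human():
    """Human parameter set (allometric, human in vitro Kd)."""
    return human_parameters()


@pytest.fixture(scope="session")
def iiv():
    return monkey_iiv()


@pytest.fixture(scope="session")
def resid():
    return monkey_residual_error()
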