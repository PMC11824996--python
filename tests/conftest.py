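import numpy as np
import pytest

from oncofrac import (FractionalOrder, ModelParameters, scale_parameters)

#: baseline initial state used throughout the study scenarios
Y0 = np.array([2.0, 0.1, 1.0, 0.5, 0.5])


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """Baseline biological parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def sp1(params):
    """Baseline parameters at the classical limit alpha = 1."""
    return scale_parameters(params, FractionalOrder(1.0))


@pytest.fixture(scope="session")
def sp085(params):
    return scale_parameters(params, FractionalOrder(0.85))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def y0() -> np.ndarray:
    return Y0.copy()
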