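import warnings

import pytest

from turingtda import (
    Model,
    ModelParams,
    build_grid,
    linearise,
    triangulate_grid,
)


@pytest.fixture(scope="session")
def grid41():
    """The production grid: 20 x 20 domain at stepsize 0.5."""
    return build_grid(20.0, 20.0, 0.5)


@pytest.fixture(scope="session")
def complex41(grid41):
    return triangulate_grid(grid41)


@pytest.fixture(scope="session")
def cima_in_space():
    """A CIMA parameter point well inside the Turing space."""
    return ModelParams(Model.CIMA, alpha=10.0, beta=0.3, delta=1.5, sigma=20.0)


@pytest.fixture(scope="session")
def cima_lin(cima_in_space):
    return linearise(cima_in_space)


@pytest.fixture(autouse=True)
def _quiet_nyquist_warnings():
    """Coarse-grid tests intentionally violate the stepsize bound."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="stepsize .* exceeds")
        yield
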