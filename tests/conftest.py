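import numpy as np
import pytest

from latentlangevin import LatentModel, make_grid


@pytest.fixture(scope="session")
def grid64():
    return make_grid(64)


@pytest.fixture(scope="session")
def grid32():
    return make_grid(32)


@pytest.fixture(scope="session")
def grid16():
    return make_grid(16)


def quadratic_model(grid, boundary="reflecting", noise=0.5):
    """Smooth single-well model used across operator tests."""
    return LatentModel.from_functions(
        grid,
        lambda x: x**2,
        noise,
        lambda x: np.exp(-(x**2) / 0.05),
        lambda x: 10.0 + 5.0 * x,
        boundary,
    )


@pytest.fixture(scope="session")
def well_reflecting(grid64):
    return quadratic_model(grid64, "reflecting")


@pytest.fixture(scope="session")
def well_absorbing(grid64):
    return quadratic_model(grid64, "absorbing")
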