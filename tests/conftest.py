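import numpy as np
import pytest

from colornaming import (
    capacity_prior,
    compute_frontier,
    gaussian_meanings,
    make_fixture_bundle,
    make_grid_universe,
)


@pytest.fixture(scope="session")
def toy_universe():
    return make_grid_universe(8, 8, spacing=10.0)


@pytest.fixture(scope="session")
def toy_meanings(toy_universe):
    """Gaussian meanings with the capacity-achieving prior (the scoring model)."""
    return capacity_prior(gaussian_meanings(toy_universe, 64.0))


@pytest.fixture(scope="session")
def toy_frontier(toy_meanings):
    return compute_frontier(toy_meanings)


@pytest.fixture(scope="session")
def bundle():
    return make_fixture_bundle(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
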