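import numpy as np
import pytest

from capform import (
    Grid,
    ModelParams,
    fourier_spectrum,
    load_preset,
    make_bump_profile,
)


@pytest.fixture(scope="session")
def example():
    """The worked-example preset: quartic bump, eps=0.05, K=0.1, D_eta=0.25."""
    return load_preset("example2013")


@pytest.fixture(scope="session")
def quartic():
    return make_bump_profile(2)


@pytest.fixture(scope="session")
def example_spectrum(example):
    return fourier_spectrum(example.config.theta, example.config.K, N=200)


@pytest.fixture(scope="session")
def grid101():
    return Grid(101)


@pytest.fixture
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def ygrid():
    return np.linspace(0.0, 1.0, 101)
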