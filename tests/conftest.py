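import numpy as np
import pytest
from hypothesis import settings

from spinshield import ModelParams, build_geometry

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return ModelParams()


@pytest.fixture(scope="session")
def star3():
    return build_geometry(3, "vanishing")


@pytest.fixture(scope="session")
def complete2():
    return build_geometry(2, "maximal")


@pytest.fixture(scope="session")
def complete3():
    return build_geometry(3, "maximal")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_density_matrix(rng, dim):
    a = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    rho = a @ a.conj().T
    return rho / np.trace(rho).real


def random_unitary(rng, dim):
    a = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    q, r = np.linalg.qr(a)
    return q * (np.diag(r) / np.abs(np.diag(r)))
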