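import numpy as np
import pytest

from hfevert.parameters import MaterialParameters, default_parameters
from hfevert.phantom import fixture_suite


@pytest.fixture(scope="session")
def params() -> MaterialParameters:
    return default_parameters()


@pytest.fixture(scope="session")
def fixtures() -> dict:
    return fixture_suite()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation via QR."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
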