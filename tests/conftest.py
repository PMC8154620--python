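import numpy as np
import pytest

from cgtkit.descriptors import segment_chain
from cgtkit.synthetic import default_substate_templates


@pytest.fixture(scope="session")
def templates():
    """Four 20-bead reference conformations [C0, C1, G1, G0]."""
    return default_substate_templates(20)


@pytest.fixture(scope="session")
def segment_model():
    return segment_chain(20, 3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation matrix via QR."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q
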