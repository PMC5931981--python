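import numpy as np
import pytest
from hypothesis import settings

from ppisig.discovery import load_reference, default_reference_path

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference():
    """The bundled synthetic stand-in reference annotation."""
    return load_reference(default_reference_path())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng) -> np.ndarray:
    """Uniform-ish proper rotation matrix for rigid-invariance checks."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
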