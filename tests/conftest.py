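import numpy as np
import pytest

from quadbind import GeometryRecipe, build_ideal_duplex, build_ideal_g4


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def duplex14():
    """Idealized 14-mer poly-d(A).poly-d(T) duplex, fiber-model B geometry."""
    return build_ideal_duplex(GeometryRecipe("duplex", sequence="A" * 14))


@pytest.fixture
def g4_parallel():
    return build_ideal_g4(GeometryRecipe("g4", n_tetrads=3, topology="parallel"))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
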