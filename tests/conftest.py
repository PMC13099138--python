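import numpy as np
import pytest

from ppiscreen.synth import make_chain, make_complex, make_confidence


@pytest.fixture(scope="session")
def helix_pair():
    a = make_chain(20, "H", seed=1, chain_id="A")
    b = make_chain(20, "H", seed=2, chain_id="B")
    return a, b


@pytest.fixture(scope="session")
def docked(helix_pair):
    a, b = helix_pair
    return make_complex([a, b], "docked", seed=3, complex_id="cpx")


@pytest.fixture(scope="session")
def clashed(helix_pair):
    a, b = helix_pair
    return make_complex([a, b], "clashed", seed=3, complex_id="cpx")


@pytest.fixture(scope="session")
def separated(helix_pair):
    a, b = helix_pair
    return make_complex([a, b], "separated", seed=3, complex_id="cpx")


@pytest.fixture(scope="session")
def confident_bundle(docked):
    return make_confidence(docked, "confident_interface", seed=4)


@pytest.fixture(scope="session")
def uncertain_bundle(docked):
    return make_confidence(docked, "uncertain_interface", seed=4)


def random_rigid(seed):
    """A random proper rotation + translation."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.normal(scale=20.0, size=3)
    return R, t
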