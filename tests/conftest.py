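import numpy as np
import pytest

from invadosim import make_fixture


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_state():
    """One shared miniature simulation state (do not mutate in place)."""
    return make_fixture("tiny", seed=7)


def central_gradient(energy, x, h=1e-3):
    """-dE/dx by central differences for an (n, 3) coordinate array."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for i in range(x.shape[0]):
        for k in range(3):
            xp = x.copy()
            xm = x.copy()
            xp[i, k] += h
            xm[i, k] -= h
            g[i, k] = -(energy(xp) - energy(xm)) / (2 * h)
    return g
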