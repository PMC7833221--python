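import numpy as np
import pytest

from emergence.prob import ProbabilityTable
from emergence.toys import parity_of_states


@pytest.fixture(scope="session")
def gol_library():
    from emergence.gol import build_library

    return build_library()


@pytest.fixture
def xor_table():
    """Y = X1 xor X2 with uniform independent binary sources."""
    m = np.zeros((2, 2, 2))
    for a in range(2):
        for b in range(2):
            m[a, b, a ^ b] = 0.25
    return ProbabilityTable(("x1", "x2", "y"), m)


def random_kernel_table(rng, n, concentration=1.0):
    """Random Markov kernel on n bits with uniform initial state, as a
    joint table over (x1..xn, x1'..xn')."""
    m = 1 << n
    kernel = rng.dirichlet(np.full(m, concentration), size=m)
    joint = (kernel / m).reshape((2,) * (2 * n), order="F")
    names = tuple(f"x{i + 1}" for i in range(n)) + tuple(
        f"x{i + 1}'" for i in range(n)
    )
    return ProbabilityTable(names, joint, check=False)


def random_feature_table(rng, n, concentration=1.0, feature=None):
    """Random kernel plus a deterministic binary feature applied at both
    times; table over (v, x1..xn, v', x1'..xn')."""
    m = 1 << n
    kernel = rng.dirichlet(np.full(m, concentration), size=m)
    if feature is None:
        feature = rng.integers(0, 2, size=m)
        while feature.min() == feature.max():
            feature = rng.integers(0, 2, size=m)
    fk = np.zeros((m, 2))
    fk[np.arange(m), feature] = 1.0
    joint = kernel / m
    j4 = (
        joint[None, :, None, :]
        * fk.T[:, :, None, None]
        * fk.T[None, None, :, :]
    )
    masses = j4.reshape((2,) + (2,) * n + (2,) + (2,) * n, order="F")
    past = tuple(f"x{i + 1}" for i in range(n))
    future = tuple(f"x{i + 1}'" for i in range(n))
    return ProbabilityTable(("v",) + past + ("v'",) + future, masses, check=False)


def parity_feature(n):
    return parity_of_states(np.arange(1 << n), n)
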