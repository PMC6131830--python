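import numpy as np
import pytest

from neuroinfo.discretize import JointDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_joint(shape, rng, sparsity=0.0):
    """A random joint table (Dirichlet); optionally zero out some states."""
    n = int(np.prod(shape))
    p = rng.dirichlet(np.ones(n))
    if sparsity:
        kill = rng.random(n) < sparsity
        if kill.all():
            kill[rng.integers(n)] = False
        p[kill] = 0.0
        p /= p.sum()
    return JointDistribution(p.reshape(shape))


@pytest.fixture
def dependent_coins():
    """Joint table of two linked coins: matching faces 0.4 each, 0.1 else."""
    return JointDistribution(np.array([[0.4, 0.1], [0.1, 0.4]]))


@pytest.fixture
def quantity_pid_table():
    """Four equiprobable (x1, x2, y) triples with y = 2*x2 + x1: each source
    resolves one bit of a different y partition, giving R = S = 1 bit."""
    p = np.zeros((2, 2, 4))
    for x1, x2 in ((0, 0), (1, 0), (0, 1), (1, 1)):
        p[x1, x2, 2 * x2 + x1] = 0.25
    return JointDistribution(p)
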