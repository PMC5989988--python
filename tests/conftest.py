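import numpy as np
import pytest

from tractonet import Connectome, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def chain_phantom():
    """Three-node chain phantom: bundles 0-1 and 1-2, 50 streamlines each,
    20 mm long, seeded at 25 seeds per voxel."""
    return make_phantom(PhantomSpec(n_nodes=3, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_connectome(rng, n, density=0.5, scale=1.0):
    """Random symmetric nonnegative zero-diagonal test matrix."""
    W = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    W[iu] = np.where(present, rng.random(len(iu[0])) * scale, 0.0)
    W += W.T
    return Connectome([f"n{k}" for k in range(n)], W)
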