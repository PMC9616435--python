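import numpy as np
import pytest

import fcbm


@pytest.fixture
def two_block_partition():
    """Four vertices split into two blocks of two."""
    return fcbm.BlockPartition(assignment=np.array([0, 0, 1, 1]))


@pytest.fixture
def two_block_constraints(two_block_partition):
    """The hand-checked p=0.1 configuration on two blocks of two."""
    delta = fcbm.MixingDensityMatrix(np.array([[0.8, 0.2], [0.2, 0.8]]))
    f = np.ones(4)
    return fcbm.build_constraints(0.1, delta, f, two_block_partition)


@pytest.fixture
def toy_city_config():
    """A small stylized city that builds in well under a second."""
    return fcbm.CityConfig(
        N=400, radius_km=1.0, tile_side_km=0.5, target_mu=8.0,
        age_fractions=(0.5, 0.5), age_groups=("young", "old"), seed=11,
    )


def random_valid_configuration(rng, N=None, n=None):
    """A random feasible (p, delta, f, partition) tuple for property tests."""
    N = N or rng.integers(4, 30)
    n = n or rng.integers(1, min(5, N // 2) + 1)
    # every block non-empty
    assignment = np.concatenate([np.arange(n), rng.integers(0, n, N - n)])
    rng.shuffle(assignment)
    part = fcbm.BlockPartition(assignment=assignment, n=n)
    w = rng.random((n, n)) + 0.05
    w = (w + w.T) / 2
    sizes = part.sizes
    np.fill_diagonal(w, np.where(sizes > 1, np.diag(w), 0.0))
    delta = w / w.sum() * 2.0
    f = rng.lognormal(size=N)
    p = rng.uniform(0.01, 0.2)
    return p, fcbm.MixingDensityMatrix(delta), f, part
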