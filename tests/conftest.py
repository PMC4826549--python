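import numpy as np
import pytest

import groupsel as gs


@pytest.fixture
def toy():
    """The 8x4 two-group worked example."""
    return gs.toy_fixture()


@pytest.fixture
def small_planted():
    """Two groups of four features each, noiseless planted representatives."""
    spec = gs.SyntheticSpec(M=40, G=2, group_size=4, noise_fractions=0.0,
                            seed=11)
    return gs.generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_instance(rng, M=12, sizes=(3, 4, 2)):
    """A small random continuous instance with its group structure."""
    N = sum(sizes)
    values = rng.standard_normal((M, N))
    labels = np.where(np.arange(M) % 2 == 0, 1, -1)
    X = gs.LabeledMatrix(values, labels)
    groups = gs.GroupStructure(np.repeat(np.arange(len(sizes)), sizes))
    return X, groups
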