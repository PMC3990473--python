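import numpy as np
import pytest

from virtualcell.fixtures import make_viable_genome, random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture
def viable_genome():
    return make_viable_genome()


@pytest.fixture
def small_random_genome(rng):
    return random_genome(rng, n_genes=20)
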