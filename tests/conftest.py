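import numpy as np
import pytest

from bchrom.simulate import (
    default_blueprint,
    fragment_scaffolds,
    make_genome,
    make_line_panel,
    make_repeat_library,
)


@pytest.fixture(scope="session")
def library():
    return make_repeat_library(seed=11)


@pytest.fixture(scope="session")
def small_genome():
    """A compact genome (300-kb B, 2 x 60-kb A) shared across tests."""
    return make_genome(default_blueprint(300_000), seed=11, a_length=60_000,
                       n_transposed_genes=8)


@pytest.fixture(scope="session")
def small_scaffolds(small_genome):
    return fragment_scaffolds(small_genome, n_scaffolds=8, min_len=10_000,
                              seed=12)


@pytest.fixture(scope="session")
def small_panel(small_genome):
    return make_line_panel(small_genome, n_terminal=4, n_mini=1, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
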