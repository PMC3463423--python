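import numpy as np
import pytest

from codonheg import FixtureSpec, bacterial_code, default_catalog, generate_fixture


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def code():
    return bacterial_code()


@pytest.fixture(scope="session")
def small_fixture():
    """A small planted genome with all 40 genes (seed 11, 40-codon bodies)."""
    spec = FixtureSpec(seed=11, gene_length=40)
    genome, table = generate_fixture(spec)
    return spec, genome, table


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
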