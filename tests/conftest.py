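import numpy as np
import pytest

from damloop import build_fragment_map, simulate_genome


@pytest.fixture(scope="session")
def small_genome():
    """Two small chromosomes with ~200 bp GATC spacing."""
    return simulate_genome(2, [30_000, 20_000], 200, seed=42)


@pytest.fixture(scope="session")
def small_fmap(small_genome):
    return build_fragment_map(small_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
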