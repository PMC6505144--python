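import numpy as np
import pytest

from mirtissue.synth import SyntheticGenomeSpec, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """Fast test-sized genome with every architecture feature planted."""
    return generate_genome(SyntheticGenomeSpec.small(seed=11))


@pytest.fixture(scope="session")
def default_genome():
    """The full study-condition genome (139 retained loci, 16 clusters)."""
    return generate_genome(SyntheticGenomeSpec.default(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
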