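import numpy as np
import pytest

import chipdesign as cd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def snp_genome():
    """10 kb genome with 20 het SNPs, no indels (identity coordinate maps)."""
    return cd.generate_genome(10_000, 20, indel_rate=0.0, seed=1)


@pytest.fixture(scope="session")
def indel_genome():
    """10 kb genome with SNPs plus short indels (non-trivial liftover)."""
    return cd.generate_genome(10_000, 20, indel_rate=0.2, seed=7)


@pytest.fixture(scope="session")
def plain_genome():
    """Variant-free 10 kb genome."""
    return cd.generate_genome(10_000, 0, seed=3)
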