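import numpy as np
import pytest

from mitopop.haplotypes import load_example_counts, load_example_pooled_counts


@pytest.fixture(scope="session")
def example_table():
    """Bundled 11-population COI haplotype count table."""
    return load_example_counts()


@pytest.fixture(scope="session")
def pooled_counts():
    """The survey's printed pooled (entire-region) haplotype counts."""
    return load_example_pooled_counts()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
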