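import numpy as np
import pytest

from viriscape import simgen


@pytest.fixture(scope="session")
def small_genome():
    """A 50-kb two-contig genome reused by read/k-mer tests."""
    return simgen.make_random_genome(
        {"chrA": 30_000, "chrB": 20_000},
        seed=7,
        contig_class={"chrA": "A", "chrB": "A"},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
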