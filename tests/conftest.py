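import numpy as np
import pytest

from proteorf import synthetic


@pytest.fixture(scope="session")
def truth():
    """One seeded toy genome with 3 missed-intron and 2 missing-gene errors."""
    return synthetic.generate_genome(
        n_genes=20, n_missed_intron=3, n_missing_gene=2, seed=11
    )


@pytest.fixture(scope="session")
def observations(truth):
    return synthetic.simulate_observations(truth, coverage=0.8, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(2011)


def random_contig_sequence(rng, n):
    return "".join(rng.choice(("A", "C", "G", "T"), size=n))
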