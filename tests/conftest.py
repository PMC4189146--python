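import numpy as np
import pytest

from txeval import homology, synthetic
from txeval.seqio import FastqRead


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_ref():
    """20 genes, 1-3 isoforms each, proteins of 100-300 aa."""
    return synthetic.generate_reference(20, isoforms_per_gene=(1, 3),
                                        protein_length=(100, 300), seed=11)


@pytest.fixture(scope="session")
def small_db(small_ref):
    return homology.ProteinDB(small_ref.protein_lengths, small_ref.gene_of)


def random_read(rng, length=60, name="r"):
    seq = "".join(rng.choice(list("ACGT"), length))
    return FastqRead(name, seq, "I" * length)
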