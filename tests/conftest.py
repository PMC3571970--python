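import numpy as np
import pytest

from endoreg.genome_model import AnnotatedGenome, GeneRecord, TURecord


def make_genome(sequence, genes=(), tus=(), circular=True, categories=None):
    return AnnotatedGenome(
        sequence=sequence,
        genes=[GeneRecord(*g) for g in genes],
        tus=[TURecord(t[0], tuple(t[1]), t[2]) for t in tus],
        categories=categories or {},
        circular=circular,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_genome():
    """10 bp circular genome with one + gene, matching simple arithmetic."""
    return make_genome("AAAACGTTTT", genes=[("gA", 4, 7, "+", "coding")])


def random_seq(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
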