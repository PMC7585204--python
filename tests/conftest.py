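import numpy as np
import pytest

from mtspectrum.circular import CircularGenome, GeneAnnotation


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_genome():
    """A 60-bp genome with three genes, one spanning the origin."""
    rng = np.random.default_rng(7)
    seq = random_sequence(rng, 60)
    genes = (
        GeneAnnotation("geneA", 5, 20, "protein"),
        GeneAnnotation("geneB", 25, 40, "tRNA"),
        GeneAnnotation("wrapper", 55, 3, "NCR"),  # spans the origin
    )
    return CircularGenome("toy", seq, genes)
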