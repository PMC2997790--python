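import numpy as np
import pytest

from dgetag.index import ReferenceUnigene, build_tag_index

BASES = "ACGT"


def random_seq(rng, length):
    return "".join(rng.choice(list(BASES), size=length))


def random_tag(rng):
    return "CATG" + random_seq(rng, 17)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_reference(rng):
    """Twenty random unigenes, each guaranteed at least one tag site."""
    genes = []
    for i in range(20):
        body = random_seq(rng, int(rng.integers(60, 200)))
        seq = body + random_tag(rng)
        genes.append(ReferenceUnigene(f"g{i}", seq))
    return genes


@pytest.fixture
def small_index(small_reference):
    return build_tag_index(small_reference, both_strands=True)
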