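import numpy as np
import pytest

from mutmotif.refgenome import ReferenceGenome
from mutmotif.synthetic_data import generate_genome


@pytest.fixture
def toy_genome():
    """Small handwritten genome with known gCn sites."""
    #            123456789012345678901234
    return ReferenceGenome({"chr1": "TAGCATTTGCAAACGTACGTGGCA",
                            "chr2": "ACGTACGTAC"})


@pytest.fixture
def random_genome():
    return generate_genome(20_000, gc_fraction=0.38, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
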