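import numpy as np
import pytest

from g0mosaic import PRINCIPAL_GUIDES
from g0mosaic.fixtures import (
    exon3_local_model,
    exon6_amplicon_model,
    exon6_local_model,
    three_exon_model,
)


@pytest.fixture(scope="session")
def e6_guide():
    return PRINCIPAL_GUIDES["gAdprhl1-e6-1"]


@pytest.fixture(scope="session")
def e6_local():
    return exon6_local_model()


@pytest.fixture(scope="session")
def e6_amplicons():
    return [exon6_amplicon_model("S"), exon6_amplicon_model("L")]


@pytest.fixture(scope="session")
def e3_local():
    return exon3_local_model()


@pytest.fixture(scope="session")
def splice_model():
    return three_exon_model()


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
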