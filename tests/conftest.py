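import numpy as np
import pytest

from ltsmscan import CANONICAL_LTSM, TRIPARTITE_LTSM


@pytest.fixture
def canonical():
    return CANONICAL_LTSM


@pytest.fixture
def tripartite():
    return TRIPARTITE_LTSM


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_seq(rng, length, alphabet="ACGT", p=None):
    return "".join(rng.choice(list(alphabet), size=length, p=p))
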