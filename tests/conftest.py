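import numpy as np
import pytest

from polyamp.classify import build_kmer_model
from polyamp.io import Kingdom
from polyamp.synthetic import make_reference_db


@pytest.fixture(scope="session")
def small_db():
    """A compact, well-separated reference set shared across tests."""
    return make_reference_db(n_bact=6, n_fungi=4, seed=11)


@pytest.fixture(scope="session")
def models(small_db):
    return {
        Kingdom.bacteria: build_kmer_model(small_db.bacteria),
        Kingdom.fungi: build_kmer_model(small_db.fungi),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
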