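import numpy as np
import pytest

from phosctx.embedding import EmbeddingHyperparams, train_embedding
from phosctx.seqio import build_corpus
from phosctx.synthetic import MotifSpec, generate_synthetic_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """40 background-only proteins plus annotations from a planted PKA-like motif."""
    return generate_synthetic_proteome(
        40, (60, 100), MotifSpec(fraction=0.4), seed=11
    )


@pytest.fixture(scope="session")
def toy_model(small_proteome):
    """A small trained embedding shared across tests (dim 32, 15 epochs)."""
    records, _ = small_proteome
    corpus = build_corpus(records, 3)
    hp = EmbeddingHyperparams(dim=32, window=8, epochs=15)
    return train_embedding(corpus, hp, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
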