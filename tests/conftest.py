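import numpy as np
import pytest

from discernet.corpus_io import Article, Sentence
from discernet.embeddings import EmbedderConfig, make_embedder


@pytest.fixture(scope="session")
def hashed_embedder():
    return make_embedder(EmbedderConfig(dim=8, seed=0))


def random_article(rng: np.random.Generator, doc_id: str = "doc0",
                   n_sentences: int | None = None,
                   max_tokens: int = 6) -> Article:
    """Small random article over a fixed toy vocabulary."""
    vocab = list("abcdefghij")
    n_sentences = n_sentences or int(rng.integers(1, 5))
    sentences = []
    for j in range(n_sentences):
        toks = tuple(rng.choice(vocab, size=int(rng.integers(2, max_tokens + 1))))
        sentences.append(Sentence(j, toks, " ".join(toks)))
    return Article(doc_id, "other", tuple(sentences))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
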