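import numpy as np
import pytest

import dilitopics
from dilitopics.corpus import BowCorpus, Vocabulary
from dilitopics.pipeline import load_theta_tsv


@pytest.fixture(scope="session")
def table1():
    """The packaged 26-drug published worked example: (theta, doc_ids, labels)."""
    return load_theta_tsv(dilitopics.table1_theta_path())


@pytest.fixture(scope="session")
def table1_seeds():
    with open(dilitopics.table1_seed_path()) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


@pytest.fixture
def tiny_corpus():
    """2 documents x 2 tokens over a 2-word vocabulary: small enough that the
    collapsed posterior over the 16 assignment configurations is enumerable."""
    return BowCorpus(
        Vocabulary(["a", "b"]),
        [np.array([0, 1], dtype=np.int32), np.array([1, 1], dtype=np.int32)],
        ["d0", "d1"],
    )


def random_bow(rng: np.random.Generator, n_docs=4, vocab_size=6, max_len=12) -> BowCorpus:
    """Small random bag-of-words corpus for property tests."""
    vocab = Vocabulary([f"word{i}" for i in range(vocab_size)])
    docs = [
        rng.integers(0, vocab_size, size=rng.integers(1, max_len + 1)).astype(np.int32)
        for _ in range(n_docs)
    ]
    return BowCorpus(vocab, docs, [f"doc{i}" for i in range(n_docs)])
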