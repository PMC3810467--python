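import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import memscale as ms

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_space(vectors, words=None):
    """Space from explicit (unnormalised) vectors; rows are normalised."""
    arr = np.asarray(vectors, dtype=float)
    arr = arr / np.linalg.norm(arr, axis=1, keepdims=True)
    words = words or [f"w{i}" for i in range(len(arr))]
    return ms.SemanticSpace(words=tuple(words), vectors=arr, k=arr.shape[1])


@pytest.fixture
def tiny_vocab():
    return ms.Vocabulary(words=("a", "b", "c", "d", "e"), row_size=5, col_size=5)


@pytest.fixture(scope="session")
def default_bundle():
    """One default-configuration synthetic bundle, shared across tests."""
    return ms.generate_bundle(ms.GeneratorConfig(), seed=42)


@pytest.fixture(scope="session")
def default_space(default_bundle):
    corpus = default_bundle.corpus
    m = ms.log_normalize(ms.count_cooccurrences(corpus.records, corpus.vocabulary))
    return ms.build_space(m, 16)


def brute_force_cooccurrence(records, row_words, col_words):
    """Independent pair-enumeration oracle for the co-occurrence counts."""
    counts = np.zeros((len(row_words), len(col_words)))
    ri = {w: i for i, w in enumerate(row_words)}
    ci = {w: i for i, w in enumerate(col_words)}
    for tokens, count in records:
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                if tokens[i] in ri and tokens[j] in ci:
                    counts[ri[tokens[i]], ci[tokens[j]]] += (5 - abs(i - j)) * count
    return counts
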