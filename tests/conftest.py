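"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from emobody.corpus import Corpus, Document, parse_token


def make_doc(keys, doc_id="d0", language="Akkadian", period="Neo-Assyrian"):
    return Document(
        id=doc_id,
        language=language,
        period=period,
        tokens=[parse_token(k) for k in keys],
    )


def make_corpus(docs_keys):
    return Corpus(
        documents=[make_doc(keys, doc_id=f"d{i}") for i, keys in enumerate(docs_keys)]
    )


def word(i: int) -> str:
    return f"w{i}[g{i}]N"


def random_corpus(rng: np.random.Generator, max_tokens=500, max_vocab=20,
                  empty_fraction=0.1):
    """Random multi-document corpus of small-vocabulary tokens with some
    empty-token placeholders mixed in."""
    n_tokens = int(rng.integers(10, max_tokens + 1))
    vocab = int(rng.integers(2, max_vocab + 1))
    n_docs = int(rng.integers(1, 6))
    cuts = np.sort(rng.choice(np.arange(1, n_tokens), size=n_docs - 1, replace=False)) if n_docs > 1 else np.array([], dtype=int)
    keys = [word(int(i)) for i in rng.integers(0, vocab, size=n_tokens)]
    empties = rng.random(n_tokens) < empty_fraction
    keys = ["_" if e else k for k, e in zip(keys, empties)]
    docs = []
    start = 0
    for end in list(cuts) + [n_tokens]:
        docs.append(keys[start:end])
        start = end
    return make_corpus([d for d in docs if d])


def brute_force_cooccurrence(corpus: Corpus, window: int) -> dict[tuple[str, str], int]:
    """O(n^2) enumeration of directed within-window observations (the
    counting oracle): all ordered position pairs i != j with |i - j| <=
    window, same document, both tokens non-empty, symmetrized into
    C[x,y] = A[x,y] + A[y,x]."""
    directed: dict[tuple[str, str], int] = {}
    for doc in corpus:
        keys = [None if t.is_empty else t.key() for t in doc.tokens]
        n = len(keys)
        for i in range(n):
            if keys[i] is None:
                continue
            for j in range(n):
                if j == i or abs(i - j) > window or keys[j] is None:
                    continue
                pair = (keys[i], keys[j])
                directed[pair] = directed.get(pair, 0) + 1
    counts: dict[tuple[str, str], int] = {}
    for (a, b), v in directed.items():
        counts[(a, b)] = counts.get((a, b), 0) + v
        counts[(b, a)] = counts.get((b, a), 0) + v
    return counts


@pytest.fixture(scope="session")
def primitive_atlas():
    from emobody.atlas import make_primitive_atlas

    return make_primitive_atlas()


@pytest.fixture(scope="session")
def planted_run():
    """One planted-corpus pipeline run (seed 1): spec, corpus, lexicons,
    embedding space."""
    import emobody as eb

    spec = eb.default_spec(seed=1)
    corpus = eb.generate_corpus(spec)
    emotions, bodies = eb.generate_lexicons(spec)
    space = eb.build_space(corpus)
    return spec, corpus, emotions, bodies, space
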