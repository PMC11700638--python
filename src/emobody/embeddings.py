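"""Windowed co-occurrence counts, thresholded PMI and truncated-SVD vectors.

The semantic space is built in three steps, tuned for small, repetitive,
punctuation-free corpora such as lemmatized Akkadian:

1. **Co-occurrence.** Every ordered pair of non-empty tokens within ``w``
   positions of each other (same document; windows never cross document
   boundaries) increments a symmetric count matrix.  Empty ``_`` tokens occupy
   window slots but form no pairs — a broken sign still consumes textual
   distance.  Words occurring fewer than ``min_count`` times are removed from
   the vocabulary before counting.

2. **PMI with a negative threshold.**  ``PMI(a,b) = log2(p(a,b)/(p(a)p(b)))``
   with probabilities estimated from pair counts; scores at or below
   ``-threshold`` (default 5) — including the -inf of never-co-occurring
   pairs — are treated as no association and zeroed, yielding a sparse matrix.
   Words whose entire row is zeroed end up with empty vectors and are
   discarded.

3. **Truncated SVD.**  The clamped PMI matrix is factorized and each word is
   represented by the corresponding row of ``U_k S_k`` (the classical LSA
   convention, which preserves row inner products at full rank).  Singular
   vector signs are fixed deterministically so identical inputs give
   bit-identical ``.vec`` files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import scipy.sparse as sp
from scipy.linalg import svd as _dense_svd

from .corpus import Corpus, CorpusError

logger = logging.getLogger(__name__)


class VecFormatError(ValueError):
    """A ``.vec`` file violates the ``V k`` header / row-arity contract."""


@dataclass
class Vocabulary:
    """Dense word-key ↔ integer-id map with per-word occurrence counts."""

    words: list[str]
    counts: np.ndarray  # occurrence count per word, aligned with `words`
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.words)}

    @classmethod
    def from_corpus(cls, corpus: Corpus, min_count: int = 1) -> "Vocabulary":
        """Vocabulary in first-appearance order; words below min_count dropped."""
        if min_count < 1:
            raise ValueError("min_count must be >= 1")
        order: list[str] = []
        counts: dict[str, int] = {}
        for doc in corpus:
            for tok in doc.tokens:
                if tok.is_empty:
                    continue
                key = tok.key()
                if key not in counts:
                    order.append(key)
                    counts[key] = 0
                counts[key] += 1
        kept = [w for w in order if counts[w] >= min_count]
        return cls(words=kept, counts=np.array([counts[w] for w in kept], dtype=np.int64))

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def subset(self, keep: np.ndarray) -> "Vocabulary":
        words = [self.words[i] for i in keep]
        return Vocabulary(words=words, counts=self.counts[keep])


@dataclass
class CooccurrenceMatrix:
    """Symmetric sparse matrix of ordered target–context pair counts."""

    matrix: sp.csr_matrix  # V x V, int64, symmetric, diagonal allowed
    vocab: Vocabulary
    window_size: int
    min_count: int

    @property
    def total_pairs(self) -> int:
        return int(self.matrix.sum())


@dataclass
class PMIMatrix:
    """Symmetric sparse matrix of clamped PMI scores (base-2 logs)."""

    matrix: sp.csr_matrix  # V x V, float64; stored values are > -threshold
    vocab: Vocabulary
    threshold: float
    shift_type: int


@dataclass
class EmbeddingSpace:
    """Word key → k-vector map with provenance and the discarded-word log."""

    words: list[str]
    matrix: np.ndarray  # (n_words, k)
    discarded: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {w: i for i, w in enumerate(self.words)}

    @property
    def k(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return len(self.words)

    def __contains__(self, word: str) -> bool:
        return word in self.index

    def vector(self, word: str) -> np.ndarray:
        return self.matrix[self.index[word]]

    def cosine(self, a: str, b: str) -> float:
        return cosine_similarity(self.vector(a), self.vector(b))


def count_cooccurrences(
    corpus: Corpus, window_size: int = 3, min_count: int = 1
) -> CooccurrenceMatrix:
    """Count ordered co-occurrence pairs within ±window_size tokens.

    Every ordered position pair (i, j), i ≠ j, |i - j| <= window inside one
    document contributes one directed target→context observation; the matrix
    stores the symmetrized total, so a single adjacency of distinct words a, b
    yields C[a,b] = C[b,a] = 2.  Self-pairs (the same word twice inside a
    window) land on the diagonal: repetitive formulae are a real property of
    the corpora this targets.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    vocab = Vocabulary.from_corpus(corpus, min_count=min_count)
    if len(vocab) == 0:
        raise CorpusError("corpus has no non-empty tokens above min_count")
    counts: dict[tuple[int, int], int] = {}
    for doc in corpus:
        ids = [
            vocab.index.get(t.key(), -1) if not t.is_empty else -1 for t in doc.tokens
        ]
        n = len(ids)
        for i in range(n):
            a = ids[i]
            if a < 0:
                continue
            for j in range(i + 1, min(n, i + window_size + 1)):
                b = ids[j]
                if b < 0:
                    continue
                # both directed target->context observations, symmetrized:
                # each within-window contact adds 2 to C[a,b] and C[b,a]
                counts[(a, b)] = counts.get((a, b), 0) + 2
                counts[(b, a)] = counts.get((b, a), 0) + 2
    if counts:
        rows, cols = zip(*counts.keys())
        data = np.fromiter(counts.values(), dtype=np.int64, count=len(counts))
    else:
        rows, cols, data = (), (), np.array([], dtype=np.int64)
    mat = sp.csr_matrix(
        (data, (np.array(rows, dtype=np.int64), np.array(cols, dtype=np.int64))),
        shape=(len(vocab), len(vocab)),
    )
    return CooccurrenceMatrix(
        matrix=mat, vocab=vocab, window_size=window_size, min_count=min_count
    )


def compute_pmi(
    cooc: CooccurrenceMatrix, threshold: float = 5.0, shift_type: int = 0
) -> PMIMatrix:
    """Clamped pointwise mutual information of the co-occurrence matrix.

    ``PMI(a,b) = log2((C[a,b]/T) / ((R[a]/T)(R[b]/T)))`` with ``R`` the row
    (target) marginals and ``T`` the total pair count.  With ``shift_type=0``
    every score at or below ``-threshold`` is replaced by 0 and not stored;
    zero co-occurrence (PMI = -inf) is always clamped.  Other shift types are
    rejected rather than guessed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if shift_type != 0:
        raise ValueError(f"unsupported shift_type: {shift_type}")
    total = cooc.total_pairs
    if total <= 0:
        raise ValueError("co-occurrence matrix has no pairs")
    row_sums = np.asarray(cooc.matrix.sum(axis=1)).ravel().astype(np.float64)
    coo = cooc.matrix.tocoo()
    with np.errstate(divide="ignore"):
        vals = np.log2(
            coo.data.astype(np.float64) * total / (row_sums[coo.row] * row_sums[coo.col])
        )
    keep = vals > -threshold
    mat = sp.csr_matrix(
        (vals[keep], (coo.row[keep], coo.col[keep])),
        shape=cooc.matrix.shape,
    )
    mat.eliminate_zeros()
    return PMIMatrix(matrix=mat, vocab=cooc.vocab, threshold=threshold, shift_type=shift_type)


def drop_empty_rows(
    pmi: PMIMatrix, lexicon_words: Iterable[str] = ()
) -> tuple[PMIMatrix, list[str]]:
    """Remove words whose entire PMI row was clamped to zero.

    These are the words that would receive empty (all-zero) vectors — in
    practice rare words whose every score fell at or below the negative
    threshold.  Returns the reduced matrix and the dropped word keys; overlap
    with ``lexicon_words`` (e.g. the emotion/body lists) is logged.
    """
    nnz = np.diff(pmi.matrix.indptr)
    keep = np.flatnonzero(nnz > 0)
    dropped_idx = np.flatnonzero(nnz == 0)
    dropped = [pmi.vocab.words[i] for i in dropped_idx]
    lex = set(lexicon_words)
    overlap = sorted(lex.intersection(dropped))
    if dropped:
        logger.info("dropped %d empty-row words", len(dropped))
    if overlap:
        logger.warning("dropped words present in lexicons: %s", overlap)
    mat = pmi.matrix[keep][:, keep].tocsr()
    return (
        PMIMatrix(
            matrix=mat,
            vocab=pmi.vocab.subset(keep),
            threshold=pmi.threshold,
            shift_type=pmi.shift_type,
        ),
        dropped,
    )


def factorize_svd(pmi: PMIMatrix, k: int = 60, extra_provenance: dict | None = None) -> EmbeddingSpace:
    """Truncated SVD of the clamped PMI matrix; word vectors are rows of U_k·S_k.

    Singular values come in non-increasing order; each left singular vector is
    sign-fixed so its first nonzero loading is positive, making the
    factorization — and the ``.vec`` file written from it — deterministic.
    Words whose truncated vector is numerically all-zero are discarded.
    """
    n = pmi.matrix.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds vocabulary size {n}")
    dense = pmi.matrix.toarray()
    u, s, _vt = _dense_svd(dense, full_matrices=False)
    # deterministic sign convention: first nonzero loading of each singular
    # vector made positive
    for j in range(u.shape[1]):
        col = u[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            u[:, j] = -col
    vectors = u[:, :k] * s[:k]
    norms = np.linalg.norm(vectors, axis=1)
    scale = max(s[0], 1.0) if s.size else 1.0
    keep = norms > 1e-12 * scale
    discarded = [pmi.vocab.words[i] for i in np.flatnonzero(~keep)]
    if discarded:
        logger.info("discarded %d zero-vector words after truncation", len(discarded))
    provenance = {
        "min_count": pmi.vocab.counts.min() if len(pmi.vocab) else None,
        "threshold": pmi.threshold,
        "shift_type": pmi.shift_type,
        "k": k,
        "vocabulary_size": n,
    }
    if extra_provenance:
        provenance.update(extra_provenance)
    return EmbeddingSpace(
        words=[w for w, kp in zip(pmi.vocab.words, keep) if kp],
        matrix=vectors[keep],
        discarded=discarded,
        provenance=provenance,
    )


def build_space(
    corpus: Corpus,
    window_size: int = 3,
    min_count: int = 1,
    threshold: float = 5.0,
    shift_type: int = 0,
    k: int = 60,
    lexicon_words: Iterable[str] = (),
) -> EmbeddingSpace:
    """Full chain: counts → clamped PMI → empty-row drop → truncated SVD."""
    cooc = count_cooccurrences(corpus, window_size=window_size, min_count=min_count)
    pmi = compute_pmi(cooc, threshold=threshold, shift_type=shift_type)
    pmi, dropped = drop_empty_rows(pmi, lexicon_words=lexicon_words)
    k_eff = min(k, pmi.matrix.shape[0])
    space = factorize_svd(
        pmi,
        k=k_eff,
        extra_provenance={"window_size": window_size, "min_count": min_count,
                          "requested_k": k, "documents": len(corpus)},
    )
    space.discarded = dropped + space.discarded
    return space


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of two vectors; zero-norm inputs are an error (empty vectors
    were discarded upstream, so a zero norm signals a degenerate mean)."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity of a zero-norm vector is undefined")
    return float(np.dot(u, v) / (nu * nv))


def write_vec(space: EmbeddingSpace, sink: IO[str] | str | Path) -> None:
    """Write the word2vec-style text format: ``V k`` header, then one
    ``wordkey x1 ... xk`` line per word at full round-trip precision."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            write_vec(space, fh)
        return
    if len(space) == 0:
        raise ValueError("cannot write an empty embedding space")
    sink.write(f"{len(space)} {space.k}\n")
    for word, row in zip(space.words, space.matrix):
        if any(ch.isspace() for ch in word):
            raise VecFormatError(f"word key contains whitespace: {word!r}")
        sink.write(word + " " + " ".join(repr(float(x)) for x in row) + "\n")


def read_vec(source: IO[str] | str | Path) -> EmbeddingSpace:
    """Inverse of :func:`write_vec`; arity mismatches raise VecFormatError."""
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            return read_vec(fh)
    header = source.readline().split()
    if len(header) != 2:
        raise VecFormatError("header must be 'V k'")
    try:
        n, k = int(header[0]), int(header[1])
    except ValueError as exc:
        raise VecFormatError("header must hold two integers") from exc
    words: list[str] = []
    rows: list[np.ndarray] = []
    for line in source:
        parts = line.split()
        if not parts:
            continue
        if len(parts) != k + 1:
            raise VecFormatError(
                f"row for {parts[0]!r} has {len(parts) - 1} values, expected {k}"
            )
        words.append(parts[0])
        rows.append(np.array([float(x) for x in parts[1:]], dtype=np.float64))
    if len(words) != n:
        raise VecFormatError(f"header promised {n} words, file holds {len(words)}")
    return EmbeddingSpace(words=words, matrix=np.vstack(rows) if rows else np.zeros((0, k)))


def export_sparse_csv(
    matrix: sp.spmatrix, vocab: Vocabulary, sink: IO[str] | str | Path
) -> None:
    """Export stored upper-triangle entries as ``word_a,word_b,value`` CSV."""
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8") as fh:
            export_sparse_csv(matrix, vocab, fh)
        return
    coo = matrix.tocoo()
    sink.write("word_a,word_b,value\n")
    order = np.lexsort((coo.col, coo.row))
    for idx in order:
        r, c, v = int(coo.row[idx]), int(coo.col[idx]), coo.data[idx]
        if r <= c:  # symmetric matrices: store each unordered pair once
            sink.write(f"{vocab.words[r]},{vocab.words[c]},{v!r}\n")
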