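"""Co-occurrence counting, PMI, truncated SVD and the .vec format."""

import io

import numpy as np
import pytest
import scipy.sparse as sp

from emobody.corpus import CorpusError
from emobody.embeddings import (
    EmbeddingSpace,
    PMIMatrix,
    VecFormatError,
    Vocabulary,
    build_space,
    compute_pmi,
    cosine_similarity,
    count_cooccurrences,
    drop_empty_rows,
    factorize_svd,
    read_vec,
    write_vec,
)

from conftest import brute_force_cooccurrence, make_corpus, random_corpus, word


def pair_count(cooc, a, b):
    ia, ib = cooc.vocab.index[a], cooc.vocab.index[b]
    return cooc.matrix[ia, ib]


class TestCooccurrence:
    def test_window_one_adjacent_pairs_only(self):
        cooc = count_cooccurrences(make_corpus([["a[x]N", "b[x]N", "c[x]N"]]), 1)
        assert pair_count(cooc, "a[x]N", "b[x]N") == 2  # ordered pairs both ways
        assert pair_count(cooc, "b[x]N", "c[x]N") == 2
        assert pair_count(cooc, "a[x]N", "c[x]N") == 0

    def test_wide_window_reaches_distant_tokens(self):
        cooc = count_cooccurrences(make_corpus([["a[x]N", "b[x]N", "c[x]N"]]), 3)
        assert pair_count(cooc, "a[x]N", "c[x]N") == 2

    def test_windows_do_not_cross_documents(self):
        cooc = count_cooccurrences(make_corpus([["a[x]N", "b[x]N"], ["c[x]N"]]), 3)
        assert pair_count(cooc, "b[x]N", "c[x]N") == 0

    def test_empty_tokens_occupy_positions_without_pairing(self):
        docs = [["a[x]N", "_", "b[x]N"]]
        assert pair_count(count_cooccurrences(make_corpus(docs), 1), "a[x]N", "b[x]N") == 0
        assert pair_count(count_cooccurrences(make_corpus(docs), 2), "a[x]N", "b[x]N") == 2

    def test_self_pairs_counted(self):
        cooc = count_cooccurrences(make_corpus([["a[x]N", "a[x]N"]]), 1)
        assert pair_count(cooc, "a[x]N", "a[x]N") == 4  # both directions, symmetrized

    def test_min_count_drops_rare_words_before_counting(self):
        docs = [["a[x]N", "rare[x]N", "a[x]N"]]
        cooc = count_cooccurrences(make_corpus(docs), 1, min_count=2)
        assert "rare[x]N" not in cooc.vocab
        # the rare word still occupies its slot: a..a are 2 apart, no pair at w=1
        assert pair_count(cooc, "a[x]N", "a[x]N") == 0

    def test_all_empty_corpus_rejected(self):
        with pytest.raises(CorpusError):
            count_cooccurrences(make_corpus([["_", "_"]]), 1)

    @pytest.mark.parametrize("window", [1, 2, 3, 5])
    def test_matches_bruteforce_enumeration(self, window):
        rng = np.random.default_rng(100 + window)
        for _ in range(10):
            corpus = random_corpus(rng)
            cooc = count_cooccurrences(corpus, window)
            expected = brute_force_cooccurrence(corpus, window)
            coo = cooc.matrix.tocoo()
            got = {
                (cooc.vocab.words[r], cooc.vocab.words[c]): int(v)
                for r, c, v in zip(coo.row, coo.col, coo.data)
                if v
            }
            assert got == expected


class TestPMI:
    def test_single_pair_worked_example_is_one_bit(self):
        cooc = count_cooccurrences(make_corpus([["a[x]N", "b[x]N"]]), 1)
        pmi = compute_pmi(cooc)
        ia, ib = pmi.vocab.index["a[x]N"], pmi.vocab.index["b[x]N"]
        assert pmi.matrix[ia, ib] == 1.0
        assert pmi.matrix[ib, ia] == 1.0

    def test_never_cooccurring_pair_stored_as_zero(self):
        corpus = make_corpus([["a[x]N", "b[x]N"], ["c[x]N", "d[x]N"]])
        pmi = compute_pmi(count_cooccurrences(corpus, 1))
        ia, ic = pmi.vocab.index["a[x]N"], pmi.vocab.index["c[x]N"]
        assert pmi.matrix[ia, ic] == 0.0

    def test_scores_at_or_below_negative_threshold_clamped(self):
        # one a-b contact in a sea of a-a and b-b contacts drives PMI(a,b)
        # far negative; at threshold 5 a raw score of -6 or lower must vanish
        docs = [["a[x]N"] * 200, ["b[x]N"] * 200, ["a[x]N", "b[x]N"]]
        cooc = count_cooccurrences(make_corpus(docs), 1)
        raw = compute_pmi(cooc, threshold=1e9)  # effectively unclamped
        ia, ib = raw.vocab.index["a[x]N"], raw.vocab.index["b[x]N"]
        assert raw.matrix[ia, ib] <= -6.0
        clamped = compute_pmi(cooc, threshold=5.0)
        assert clamped.matrix[ia, ib] == 0.0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(7)
        corpus = random_corpus(rng)
        pmi = compute_pmi(count_cooccurrences(corpus, 3))
        diff = (pmi.matrix - pmi.matrix.T).tocoo()
        assert diff.nnz == 0 or np.all(diff.data == 0)

    def test_stored_values_exceed_negative_threshold(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            pmi = compute_pmi(count_cooccurrences(random_corpus(rng), 3), threshold=2.0)
            if pmi.matrix.nnz:
                assert np.all(pmi.matrix.data > -2.0)

    def test_parameter_validation(self):
        cooc = count_cooccurrences(make_corpus([["a[x]N", "b[x]N"]]), 1)
        with pytest.raises(ValueError):
            compute_pmi(cooc, threshold=0)
        with pytest.raises(ValueError):
            compute_pmi(cooc, shift_type=1)


class TestDropEmptyRows:
    def test_fully_clamped_word_is_dropped(self):
        # a word whose every score fell at or below the threshold has an
        # all-zero stored row; constructed directly at the matrix level
        dense = np.array([[0.0, 2.0, 0.0], [2.0, 0.5, 0.0], [0.0, 0.0, 0.0]])
        vocab = Vocabulary(words=[word(i) for i in range(3)],
                           counts=np.ones(3, dtype=np.int64))
        pmi = PMIMatrix(sp.csr_matrix(dense), vocab, 5.0, 0)
        reduced, dropped = drop_empty_rows(pmi, lexicon_words=[word(2)])
        assert dropped == [word(2)]
        assert reduced.vocab.words == [word(0), word(1)]
        np.testing.assert_array_equal(reduced.matrix.toarray(), dense[:2, :2])

    def test_no_empty_rows_drops_nothing(self):
        pmi = compute_pmi(count_cooccurrences(make_corpus([["a[x]N", "b[x]N"]]), 1))
        reduced, dropped = drop_empty_rows(pmi)
        assert dropped == []
        assert reduced.matrix.shape == pmi.matrix.shape


def _random_pmi(rng, n):
    """Random sparse symmetric matrix wrapped as a PMIMatrix."""
    dense = rng.normal(size=(n, n)) * (rng.random((n, n)) < 0.4)
    dense = np.triu(dense) + np.triu(dense, 1).T
    # ensure no all-zero rows
    for i in range(n):
        if not dense[i].any():
            j = (i + 1) % n
            dense[i, j] = dense[j, i] = 1.0
    vocab = Vocabulary(words=[word(i) for i in range(n)], counts=np.ones(n, dtype=np.int64))
    return PMIMatrix(matrix=sp.csr_matrix(dense), vocab=vocab, threshold=5.0, shift_type=0)


class TestSVD:
    def test_two_by_two_antidiagonal_gives_orthogonal_rows(self):
        vocab = Vocabulary(words=["a[x]N", "b[x]N"], counts=np.ones(2, dtype=np.int64))
        pmi = PMIMatrix(sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]])), vocab, 5.0, 0)
        space = factorize_svd(pmi, k=2)
        assert abs(cosine_similarity(space.vector("a[x]N"), space.vector("b[x]N"))) < 1e-12

    def test_rank_one_matrix_reconstructed_at_k_one(self):
        v = np.array([1.0, 2.0, 3.0])
        dense = np.outer(v, v)
        vocab = Vocabulary(words=[word(i) for i in range(3)], counts=np.ones(3, dtype=np.int64))
        pmi = PMIMatrix(sp.csr_matrix(dense), vocab, 5.0, 0)
        space = factorize_svd(pmi, k=1)
        gram = space.matrix @ space.matrix.T
        np.testing.assert_allclose(gram, dense @ dense.T, atol=1e-9)

    def test_full_rank_preserves_row_cosines(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(3, 20))
            pmi = _random_pmi(rng, n)
            space = factorize_svd(pmi, k=n)
            dense = pmi.matrix.toarray()
            for i in range(n):
                for j in range(i + 1, n):
                    want = cosine_similarity(dense[i], dense[j])
                    got = cosine_similarity(space.matrix[i], space.matrix[j])
                    assert abs(want - got) < 1e-8

    def test_k_larger_than_vocabulary_rejected(self):
        pmi = _random_pmi(np.random.default_rng(0), 4)
        with pytest.raises(ValueError):
            factorize_svd(pmi, k=5)

    def test_sign_convention_is_deterministic(self):
        pmi = _random_pmi(np.random.default_rng(5), 8)
        a = factorize_svd(pmi, k=8)
        b = factorize_svd(pmi, k=8)
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestCosine:
    def test_identical_orthogonal_antiparallel(self):
        v = np.array([1.0, 2.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == 0.0
        assert cosine_similarity(v, -v) == pytest.approx(-1.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestVecFormat:
    def test_roundtrip_exact(self):
        space = EmbeddingSpace(
            words=["a[x]N", "b[y]V"],
            matrix=np.array([[0.1, -1.5, 3e-17], [1 / 3, 2.0, -0.0]]),
        )
        buf = io.StringIO()
        write_vec(space, buf)
        text = buf.getvalue()
        assert text.splitlines()[0] == "2 3"
        assert len(text.splitlines()) == 3
        back = read_vec(io.StringIO(text))
        assert back.words == space.words
        np.testing.assert_array_equal(back.matrix, space.matrix)

    def test_row_arity_mismatch_rejected(self):
        with pytest.raises(VecFormatError):
            read_vec(io.StringIO("1 3\na[x]N 1.0 2.0\n"))

    def test_header_mismatch_rejected(self):
        with pytest.raises(VecFormatError):
            read_vec(io.StringIO("2 2\na[x]N 1.0 2.0\n"))


def test_pipeline_determinism_bit_identical_vec():
    """Identical corpus and parameters give byte-identical .vec output."""
    import emobody as eb

    spec = eb.default_spec(seed=9, background_vocab=80, n_docs=10, doc_length=80)
    outs = []
    for _ in range(2):
        corpus = eb.generate_corpus(spec)
        space = build_space(corpus, k=20)
        buf = io.StringIO()
        write_vec(space, buf)
        outs.append(buf.getvalue())
    assert outs[0] == outs[1]


def test_planted_pair_cosine_beats_background_median(planted_run):
    """Planted emotion-body pairs sit above the median emotion-body cosine."""
    spec, _corpus, emotions, bodies, space = planted_run
    from emobody.synthetic import body_word_key

    body_keys = [b.word for b in bodies if not b.mask_only and b.word in space]
    sims = {}
    for e in emotions:
        if e.word not in space:
            continue
        for b in body_keys:
            sims[(e.word, b)] = cosine_similarity(space.vector(e.word), space.vector(b))
    median = np.median(list(sims.values()))
    hits = total = 0
    for ci, cid in enumerate(spec.category_ids):
        planted_body = body_word_key(spec.body_parts[int(np.argmax(spec.affinity[ci]))])
        for w in spec.categories[cid]:
            if (w, planted_body) in sims:
                total += 1
                hits += sims[(w, planted_body)] > median
    assert total > 0 and hits / total >= 0.95
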