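"""Semantic-space construction: weights, counting, SVD, synonym test."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import memscale as ms
from memscale.errors import (
    EmptyCorpusError,
    SynonymTestError,
    UnknownWordError,
    ValidationError,
)

from conftest import brute_force_cooccurrence, make_space


class TestDistanceWeight:
    @pytest.mark.parametrize("d,expected", [(1, 4), (2, 3), (3, 2), (4, 1)])
    def test_mapping(self, d, expected):
        assert ms.distance_weight(d) == expected

    @pytest.mark.parametrize("d", [0, 5, -1])
    def test_out_of_range(self, d):
        with pytest.raises(ValidationError):
            ms.distance_weight(d)

    def test_unique_weakly_decreasing_completion(self):
        """{1->4, 4->1} extends to exactly one weakly decreasing bijection."""
        completions = [
            p for p in itertools.permutations([1, 2, 3, 4])
            if p[0] == 4 and p[3] == 1 and all(a >= b for a, b in zip(p, p[1:]))
        ]
        assert completions == [(4, 3, 2, 1)]
        assert [ms.distance_weight(d) for d in (1, 2, 3, 4)] == [4, 3, 2, 1]


class TestCountCooccurrences:
    def test_single_ngram_hand_cells(self, tiny_vocab):
        m = ms.count_cooccurrences([(("a", "b", "c", "d", "e"), 1)], tiny_vocab)
        idx = {w: i for i, w in enumerate(m.row_words)}
        assert m.counts[idx["a"], idx["e"]] == 1  # distance 4
        assert m.counts[idx["a"], idx["b"]] == 4  # distance 1
        assert m.counts[idx["c"], idx["a"]] == 3  # distance 2
        assert not m.log_normalized

    def test_repeated_word_total(self, tiny_vocab):
        m = ms.count_cooccurrences([(("a",) * 5, 1)], tiny_vocab)
        # all 20 ordered position pairs accumulate on cell (a, a):
        # 8 pairs at distance 1 (weight 4), 6 at 2 (3), 4 at 3 (2), 2 at 4 (1)
        expected = sum(
            5 - abs(i - j) for i in range(5) for j in range(5) if i != j
        )
        assert expected == 8 * 4 + 6 * 3 + 4 * 2 + 2 * 1 == 60
        idx = m.row_words.index("a")
        assert m.counts[idx, idx] == expected

    def test_oov_token_contributes_nothing(self, tiny_vocab):
        with_oov = ms.count_cooccurrences([(("a", "b", "X", "d", "e"), 1)], tiny_vocab)
        oracle = brute_force_cooccurrence(
            [(("a", "b", "X", "d", "e"), 1)], tiny_vocab.row_words, tiny_vocab.col_words
        )
        np.testing.assert_array_equal(with_oov.counts, oracle)
        idx = {w: i for i, w in enumerate(with_oov.row_words)}
        assert with_oov.counts[idx["c"], :].sum() == 0  # 'X' replaced 'c'

    def test_weight_conservation_against_enumerator(self, tiny_vocab):
        rng = np.random.default_rng(3)
        words = list(tiny_vocab.words) + ["zz"]  # include an OOV word
        records = [
            (tuple(rng.choice(words, 5)), int(rng.integers(1, 4)))
            for _ in range(50)
        ]
        m = ms.count_cooccurrences(records, tiny_vocab)
        oracle = brute_force_cooccurrence(
            records, tiny_vocab.row_words, tiny_vocab.col_words
        )
        np.testing.assert_array_equal(m.counts, oracle)
        assert m.total_mass == oracle.sum()

    def test_empty_stream_raises(self, tiny_vocab):
        with pytest.raises(EmptyCorpusError):
            ms.count_cooccurrences([], tiny_vocab)

    def test_malformed_record_raises(self, tiny_vocab):
        with pytest.raises(ValidationError):
            ms.count_cooccurrences([(("a", "b"), 1)], tiny_vocab)
        with pytest.raises(ValidationError):
            ms.count_cooccurrences([(("a", "b", "c", "d", "e"), 0)], tiny_vocab)


class TestLogNormalize:
    def test_cell_values(self, tiny_vocab):
        m = ms.count_cooccurrences([(("a", "b", "c", "d", "e"), 1)], tiny_vocab)
        m.counts[0, 0] = np.e - 1
        out = ms.log_normalize(m)
        assert out.log_normalized
        assert out.counts[0, 0] == pytest.approx(1.0)
        np.testing.assert_allclose(out.counts, np.log1p(m.counts))

    def test_zero_cells_stay_zero(self):
        m = ms.CooccurrenceMatrix(np.zeros((2, 2)), ("a", "b"), ("a", "b"))
        assert ms.log_normalize(m).counts.sum() == 0

    def test_double_application_rejected(self, tiny_vocab):
        m = ms.count_cooccurrences([(("a", "b", "c", "d", "e"), 1)], tiny_vocab)
        once = ms.log_normalize(m)
        with pytest.raises(ValidationError):
            ms.log_normalize(once)


class TestBuildSpace:
    def test_orthogonal_rows_stay_orthogonal(self):
        m = ms.CooccurrenceMatrix(
            np.eye(2), ("a", "b"), ("x", "y"), log_normalized=True
        )
        space = ms.build_space(m, 2)
        assert ms.cosine_similarity(space, "a", "b") == pytest.approx(0.0, abs=1e-9)

    def test_duplicate_rows_identical_direction(self):
        rng = np.random.default_rng(0)
        counts = rng.random((4, 3))
        counts[1] = counts[0]
        m = ms.CooccurrenceMatrix(
            counts, ("a", "b", "c", "d"), ("x", "y", "z"), log_normalized=True
        )
        space = ms.build_space(m, 3)
        assert ms.cosine_similarity(space, "a", "b") == pytest.approx(1.0, abs=1e-9)

    def test_full_rank_gram_matrix_preserved(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 9, size=(20, 10)).astype(float)
        words = tuple(f"w{i}" for i in range(20))
        m = ms.CooccurrenceMatrix(
            counts, words, tuple(f"c{j}" for j in range(10)), log_normalized=True
        )
        from memscale.space import _svd_projection

        projection, s = _svd_projection(m)
        k = 10
        np.testing.assert_allclose(
            projection[:, :k] @ projection[:, :k].T, counts @ counts.T, atol=1e-6
        )

    def test_k_beyond_rank_names_rank(self):
        counts = np.outer([1.0, 2.0, 3.0], [1.0, 0.5])  # rank 1
        m = ms.CooccurrenceMatrix(
            counts, ("a", "b", "c"), ("x", "y"), log_normalized=True
        )
        with pytest.raises(ValidationError, match="rank 1"):
            ms.build_space(m, 2)

    def test_requires_log_normalized(self):
        m = ms.CooccurrenceMatrix(np.eye(2), ("a", "b"), ("x", "y"))
        with pytest.raises(ValidationError):
            ms.build_space(m, 1)


class TestCosineSimilarity:
    def test_self_similarity_and_symmetry(self, default_space):
        w1, w2 = default_space.words[0], default_space.words[5]
        assert ms.cosine_similarity(default_space, w1, w1) == pytest.approx(1.0)
        assert ms.cosine_similarity(default_space, w1, w2) == pytest.approx(
            ms.cosine_similarity(default_space, w2, w1)
        )

    def test_matches_elementwise_sum_oracle(self, default_space):
        w1, w2 = default_space.words[1], default_space.words[9]
        v1, v2 = default_space.vector(w1), default_space.vector(w2)
        oracle = sum(float(a) * float(b) for a, b in zip(v1, v2))
        assert ms.cosine_similarity(default_space, w1, w2) == pytest.approx(
            oracle, abs=1e-12
        )
        assert -1.0 - 1e-9 <= oracle <= 1.0 + 1e-9

    def test_unknown_word_named_in_error(self, default_space):
        with pytest.raises(UnknownWordError, match="nonexistent"):
            ms.cosine_similarity(default_space, default_space.words[0], "nonexistent")


class TestSynonymTest:
    def test_identical_pair_scores_near_zero(self):
        rng = np.random.default_rng(1)
        vectors = rng.normal(size=(40, 8))
        vectors[1] = vectors[0]  # planted perfect synonym pair
        space = make_space(vectors)
        score = ms.synonym_test(space, [("w0", "w1")], n_random=200, seed=0)
        assert score < 5.0

    def test_random_pairs_score_near_chance(self):
        rng = np.random.default_rng(2)
        space = make_space(rng.normal(size=(60, 8)))
        pairs = [
            (space.words[i], space.words[j])
            for i, j in rng.integers(0, 60, size=(50, 2))
            if i != j
        ]
        score = ms.synonym_test(space, pairs, n_random=300, seed=3)
        assert 30.0 < score < 70.0

    def test_missing_words_dropped_and_all_missing_errors(self, default_space):
        w = default_space.words
        score = ms.synonym_test(
            default_space, [(w[0], w[0 + 1]), ("absent", w[2])], n_random=100, seed=0
        )
        assert 0.0 <= score <= 100.0
        with pytest.raises(SynonymTestError):
            ms.synonym_test(default_space, [("absent", "gone")], n_random=100, seed=0)

    def test_n_random_floor(self, default_space):
        with pytest.raises(ValidationError):
            ms.synonym_test(
                default_space, [(default_space.words[0], default_space.words[1])],
                n_random=10, seed=0,
            )


class TestSelectDimensionality:
    def test_singleton_grid(self, default_bundle):
        corpus = default_bundle.corpus
        m = ms.log_normalize(
            ms.count_cooccurrences(corpus.records, corpus.vocabulary)
        )
        result = ms.select_dimensionality(
            m, corpus.synonym_pairs, [1], n_random=200, seed=0
        )
        assert result.chosen_k == 1

    def test_planted_rank_recovered(self, default_bundle):
        """With 8 latent topics, the best k sits at or above the topic count."""
        corpus = default_bundle.corpus
        m = ms.log_normalize(
            ms.count_cooccurrences(corpus.records, corpus.vocabulary)
        )
        result = ms.select_dimensionality(
            m, corpus.synonym_pairs, [1, 2, 4, 8, 16], n_random=500, seed=0
        )
        assert result.chosen_k in (8, 16)
        assert result.scores[8] <= result.scores[1]

    def test_tie_prefers_smaller_k(self):
        result = ms.SynonymTestResult(
            scores={4: 1.0, 8: 1.0}, chosen_k=4, n_random=100, seed=0
        )
        assert result.chosen_k == 4
        with pytest.raises(ValidationError):
            ms.SynonymTestResult(
                scores={4: 2.0, 8: 1.0}, chosen_k=4, n_random=100, seed=0
            )

    def test_k_above_rank_annotated(self, default_bundle):
        corpus = default_bundle.corpus
        m = ms.log_normalize(
            ms.count_cooccurrences(corpus.records, corpus.vocabulary)
        )
        with pytest.raises(ValidationError, match="k=10000"):
            ms.select_dimensionality(
                m, corpus.synonym_pairs, [1, 10000], n_random=100, seed=0
            )


@given(st.integers(0, 2**16))
def test_unit_norm_invariant_over_seeds(seed):
    """Every word vector of a built space has unit norm (random matrices)."""
    rng = np.random.default_rng(seed)
    counts = rng.random((8, 5))
    m = ms.CooccurrenceMatrix(
        counts, tuple(f"w{i}" for i in range(8)), tuple(f"c{j}" for j in range(5)),
        log_normalized=True,
    )
    space = ms.build_space(m, 3)
    np.testing.assert_allclose(np.linalg.norm(space.vectors, axis=1), 1.0, atol=1e-9)
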