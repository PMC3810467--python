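"""Distributional semantic spaces from 5-gram co-occurrence statistics.

The construction follows the classic latent-semantic-analysis recipe: a
word-by-context matrix is accumulated from 5-gram windows with
distance-dependent integer weights, cells are compressed with ``log(1 + x)``,
the matrix is factored by singular value decomposition, and every word is
represented by its first *k* left-singular coordinates scaled by the singular
values and normalised to unit length.  Semantic similarity between two words
is the cosine of their vectors.

The number of dimensions *k* is chosen by a synonym test: the cosine of each
known synonym pair is ranked against the cosines of randomly drawn word
pairs, and the *k* whose median percentile rank is lowest (synonyms most
clearly closer than chance) wins.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyCorpusError,
    SynonymTestError,
    UnknownWordError,
    ValidationError,
)

log = logging.getLogger(__name__)

NGRAM_ORDER = 5

__all__ = [
    "NGRAM_ORDER",
    "Vocabulary",
    "CooccurrenceMatrix",
    "SemanticSpace",
    "SynonymTestResult",
    "distance_weight",
    "count_cooccurrences",
    "log_normalize",
    "build_space",
    "cosine_similarity",
    "synonym_test",
    "select_dimensionality",
    "default_k_grid",
]


def distance_weight(d: int) -> int:
    """Weight of a co-occurrence at token distance ``d`` within a 5-gram.

    Adjacent words (distance 1) get weight 4; words at the opposite ends of
    the window (distance 4) get weight 1; the mapping is ``5 - d``, the unique
    weakly decreasing integer completion of the published end points.
    """
    if not 1 <= d <= 4:
        raise ValidationError(f"token distance must be in [1, 4], got {d}")
    return 5 - d


@dataclass(frozen=True)
class Vocabulary:
    """Corpus words ordered by descending frequency, with row/column cut-offs.

    The ``row_size`` most frequent words index matrix rows (the words that get
    vectors); the ``col_size`` most frequent words index context columns.
    """

    words: tuple[str, ...]
    row_size: int
    col_size: int

    def __post_init__(self) -> None:
        if len(set(self.words)) != len(self.words):
            raise ValidationError("vocabulary words must be unique")
        if not self.words:
            raise ValidationError("vocabulary is empty")
        if not 1 <= self.row_size <= len(self.words):
            raise ValidationError(
                f"row_size {self.row_size} outside [1, {len(self.words)}]"
            )
        if not 1 <= self.col_size <= len(self.words):
            raise ValidationError(
                f"col_size {self.col_size} outside [1, {len(self.words)}]"
            )

    @property
    def row_words(self) -> tuple[str, ...]:
        return self.words[: self.row_size]

    @property
    def col_words(self) -> tuple[str, ...]:
        return self.words[: self.col_size]

    @classmethod
    def from_frequencies(
        cls,
        frequencies: Mapping[str, int],
        row_size: int | None = None,
        col_size: int | None = None,
    ) -> "Vocabulary":
        """Build a vocabulary from word frequencies.

        Ordering is by descending count with alphabetical tie-break so the
        result is deterministic.  ``row_size``/``col_size`` default to the
        whole vocabulary.
        """
        if not frequencies:
            raise ValidationError("no word frequencies supplied")
        words = tuple(sorted(frequencies, key=lambda w: (-frequencies[w], w)))
        n = len(words)
        return cls(
            words=words,
            row_size=n if row_size is None else min(row_size, n),
            col_size=n if col_size is None else min(col_size, n),
        )


@dataclass
class CooccurrenceMatrix:
    """Distance-weighted word-by-context counts, optionally log-compressed."""

    counts: np.ndarray  # (n_row_words, n_col_words), non-negative
    row_words: tuple[str, ...]
    col_words: tuple[str, ...]
    log_normalized: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.row_words), len(self.col_words)):
            raise ValidationError("matrix shape does not match vocabularies")
        if (self.counts < 0).any():
            raise ValidationError("co-occurrence cells must be non-negative")

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())


def count_cooccurrences(
    ngram_stream: Iterable[tuple[Sequence[str], int]],
    vocab: Vocabulary,
) -> CooccurrenceMatrix:
    """Accumulate distance-weighted co-occurrence counts from 5-gram records.

    Every ordered position pair ``(i, j)``, ``i != j``, within a 5-gram
    contributes ``distance_weight(|i - j|) * count`` to the cell indexed by
    (row word at *i*, context word at *j*), provided both words fall inside
    the respective vocabulary cut-offs.  Out-of-vocabulary tokens simply
    contribute nothing.
    """
    row_index = {w: i for i, w in enumerate(vocab.row_words)}
    col_index = {w: j for j, w in enumerate(vocab.col_words)}
    counts = np.zeros((len(row_index), len(col_index)))
    n_records = 0
    for record_no, (tokens, count) in enumerate(ngram_stream, start=1):
        if len(tokens) != NGRAM_ORDER:
            raise ValidationError(
                f"record {record_no}: expected {NGRAM_ORDER} tokens, got {len(tokens)}"
            )
        if count < 1:
            raise ValidationError(f"record {record_no}: count must be >= 1, got {count}")
        for i, wi in enumerate(tokens):
            r = row_index.get(wi)
            if r is None:
                continue
            for j, wj in enumerate(tokens):
                if i == j:
                    continue
                c = col_index.get(wj)
                if c is not None:
                    counts[r, c] += (NGRAM_ORDER - abs(i - j)) * count
        n_records += 1
    if n_records == 0:
        raise EmptyCorpusError("n-gram stream contained no records")
    return CooccurrenceMatrix(
        counts=counts,
        row_words=vocab.row_words,
        col_words=vocab.col_words,
        log_normalized=False,
    )


def log_normalize(m: CooccurrenceMatrix) -> CooccurrenceMatrix:
    """Replace every cell by ``log(cell + 1)`` (natural logarithm)."""
    if m.log_normalized:
        raise ValidationError("matrix is already log-normalized")
    return CooccurrenceMatrix(
        counts=np.log1p(m.counts),
        row_words=m.row_words,
        col_words=m.col_words,
        log_normalized=True,
    )


@dataclass
class SemanticSpace:
    """A vocabulary of unit-length *k*-dimensional word vectors."""

    words: tuple[str, ...]
    vectors: np.ndarray  # (len(words), k), rows unit-norm
    k: int
    dropped_words: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (len(self.words), self.k):
            raise ValidationError("vector matrix shape does not match words/k")
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        norms = np.linalg.norm(self.vectors, axis=1)
        if len(norms) and not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("word vectors must have unit Euclidean norm")
        self._index = {w: i for i, w in enumerate(self.words)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __len__(self) -> int:
        return len(self.words)

    def index_of(self, word: str) -> int:
        try:
            return self._index[word]
        except KeyError:
            raise UnknownWordError(word) from None

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self.index_of(word)]


def _svd_projection(m: CooccurrenceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Full thin SVD of the normalised matrix; returns (U * S, singular values)."""
    if not m.log_normalized:
        raise ValidationError("matrix must be log-normalized before SVD")
    u, s, _ = np.linalg.svd(m.counts, full_matrices=False)
    return u * s, s


def matrix_rank_from_singular_values(s: np.ndarray, shape: tuple[int, int]) -> int:
    if len(s) == 0 or s[0] == 0:
        return 0
    tol = s[0] * max(shape) * np.finfo(float).eps
    return int(np.sum(s > tol))


def _space_from_projection(
    words: Sequence[str], projection: np.ndarray, k: int, meta: dict | None = None
) -> SemanticSpace:
    proj = projection[:, :k]
    norms = np.linalg.norm(proj, axis=1)
    keep = norms > 1e-12
    dropped = tuple(w for w, ok in zip(words, keep) if not ok)
    if dropped:
        log.warning("dropping %d zero-projection rows: %s", len(dropped), dropped)
    vectors = proj[keep] / norms[keep, None]
    return SemanticSpace(
        words=tuple(w for w, ok in zip(words, keep) if ok),
        vectors=vectors,
        k=k,
        dropped_words=dropped,
        meta=dict(meta or {}),
    )


def build_space(m: CooccurrenceMatrix, k: int) -> SemanticSpace:
    """SVD-project a log-normalised matrix into a *k*-dimensional space.

    Word vectors are the first *k* coordinates of ``U @ diag(S)`` (left
    singular vectors scaled by singular values, descending order), normalised
    to unit length.  Rows whose *k*-dimensional projection is exactly zero are
    dropped from the space and recorded in ``dropped_words``.
    """
    if not 1 <= k <= min(m.counts.shape):
        raise ValidationError(
            f"k={k} outside [1, {min(m.counts.shape)}] for matrix {m.counts.shape}"
        )
    projection, s = _svd_projection(m)
    rank = matrix_rank_from_singular_values(s, m.counts.shape)
    if k > rank:
        raise ValidationError(f"k={k} exceeds the attained matrix rank {rank}")
    return _space_from_projection(m.row_words, projection, k, meta={"rank": rank})


def cosine_similarity(space: SemanticSpace, w1: str, w2: str) -> float:
    """Cosine of the angle between two word vectors (dot of unit vectors)."""
    return float(space.vector(w1) @ space.vector(w2))


def _percentile_rank(value: float, reference: np.ndarray) -> float:
    """Mid-rank percentile of ``value`` within ``reference`` (low = high cosine)."""
    greater = int(np.sum(reference > value))
    ties = int(np.sum(reference == value))
    return 100.0 * (greater + 0.5 * ties) / len(reference)


def synonym_test(
    space: SemanticSpace,
    pairs: Sequence[tuple[str, str]],
    n_random: int = 1000,
    *,
    seed: int,
) -> float:
    """Median percentile rank of synonym cosines among random-pair cosines.

    For every synonym pair present in the space, ``n_random`` random word
    pairs are drawn (with replacement, self-pairs excluded) and the synonym
    cosine's mid-rank percentile among the random cosines is computed; the
    score is the median across pairs.  Low scores mean synonyms are far more
    similar than chance; a score near 50 is chance level.
    """
    if n_random < 100:
        raise ValidationError(f"n_random must be >= 100, got {n_random}")
    if len(space) < 2:
        raise ValidationError("space must contain at least two words")
    usable, dropped = [], []
    for a, b in pairs:
        (usable if a in space and b in space else dropped).append((a, b))
    if dropped:
        log.warning("synonym pairs dropped (missing from space): %s", dropped)
    if not usable:
        raise SynonymTestError(f"no usable synonym pair; dropped: {dropped}")
    rng = np.random.default_rng(seed)
    n = len(space)
    v = space.vectors
    scores = []
    for a, b in usable:
        syn_cos = float(v[space.index_of(a)] @ v[space.index_of(b)])
        i = rng.integers(n, size=n_random)
        j = rng.integers(n, size=n_random)
        while True:  # resample self-pairs
            selfpair = i == j
            if not selfpair.any():
                break
            j[selfpair] = rng.integers(n, size=int(selfpair.sum()))
        rand_cos = np.einsum("ij,ij->i", v[i], v[j])
        scores.append(_percentile_rank(syn_cos, rand_cos))
    return float(np.median(scores))


@dataclass
class SynonymTestResult:
    """Synonym-test scores over a candidate dimensionality grid."""

    scores: dict[int, float]  # k -> median percentile score (low = good)
    chosen_k: int
    n_random: int
    seed: int

    def __post_init__(self) -> None:
        best = min(self.scores.values())
        if self.scores[self.chosen_k] != best:
            raise ValidationError("chosen_k must attain the minimum score")


def default_k_grid(max_k: int) -> tuple[int, ...]:
    """Doubling grid 1, 2, 4, 8, ... capped at ``max_k``."""
    if max_k < 1:
        raise ValidationError("max_k must be >= 1")
    grid = []
    k = 1
    while k <= max_k:
        grid.append(k)
        k *= 2
    return tuple(grid)


def select_dimensionality(
    m: CooccurrenceMatrix,
    pairs: Sequence[tuple[str, str]],
    k_grid: Sequence[int] | None = None,
    n_random: int = 1000,
    *,
    seed: int,
) -> SynonymTestResult:
    """Score a grid of dimensionalities with the synonym test and pick the best.

    A single SVD is computed and truncated per candidate *k*; the same random
    seed (hence the same random comparison pairs) is used for every *k* so the
    scores are directly comparable.  Ties go to the smaller *k*.
    """
    projection, s = _svd_projection(m)
    rank = matrix_rank_from_singular_values(s, m.counts.shape)
    if k_grid is None:
        k_grid = default_k_grid(rank)
    if not k_grid:
        raise ValidationError("k_grid is empty")
    scores: dict[int, float] = {}
    for k in sorted(set(int(k) for k in k_grid)):
        if not 1 <= k <= rank:
            raise ValidationError(f"k={k}: outside [1, rank={rank}]")
        try:
            space_k = _space_from_projection(m.row_words, projection, k)
            scores[k] = synonym_test(space_k, pairs, n_random, seed=seed)
        except (SynonymTestError, ValidationError) as exc:
            raise ValidationError(f"k={k}: {exc}") from exc
    chosen = min(scores, key=lambda k: (scores[k], k))
    return SynonymTestResult(scores=scores, chosen_k=chosen, n_random=n_random, seed=seed)
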