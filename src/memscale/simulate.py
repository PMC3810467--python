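"""Synthetic inputs with planted, recoverable structure.

A small topic model stands in for the natural-language corpus and the
experiment's narratives.  The vocabulary is partitioned into latent topics;
5-grams are drawn topic-pure (up to a small leak ``topic_leak``), so words
sharing a topic co-occur and end up close in the semantic space, and synonym
pairs are same-topic words with near-identical emission probabilities.

Narratives follow the study design: participants are split evenly over the
four cue conditions; each unimodal condition's token distribution is pulled
from a common base mixture towards a condition-specific signature topic by
the effect size; the multimodal condition is either a convex combination of
the three unimodal mixtures or additionally carries a "supra-additive"
component on a fresh topic none of the unimodal conditions uses.  Each
vocabulary word is assigned one of the 14 grammatical word classes, so the
per-class pipeline stages are exercised; classes are assigned independently
of topics and therefore carry no differential information of their own.

Defaults mirror the study's dimensions: 80 participants, 20 per condition,
15 cues each, roughly two thirds of cue presentations yielding a narrative.
"""

from __future__ import annotations

import json
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .narratives import (
    CONDITIONS,
    UNIMODAL_CONDITIONS,
    WORD_CLASSES,
    WordClassLexicon,
)
from .space import Vocabulary

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "SyntheticBundle",
    "generate_corpus",
    "generate_narratives",
    "generate_bundle",
    "condition_mixtures",
    "calibrate_effect_size",
]

# Rough word-class frequencies of running narrative text; exact values are
# immaterial because classes are independent of the planted topic signal.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "noun": 0.23,
    "verb": 0.18,
    "preposition": 0.12,
    "pronoun": 0.11,
    "adverb": 0.09,
    "adjective": 0.07,
    "conjunction": 0.06,
    "determiner": 0.05,
    "proper_name": 0.03,
    "participle": 0.02,
    "counting_word": 0.015,
    "particle": 0.015,
    "interjection": 0.005,
    "interpunction": 0.005,
}

# Signature topics: one per unimodal condition plus a reserved topic that
# only the supra-additive multimodal rule uses.
_SIGNATURE_TOPICS = {"visual": 0, "auditory": 1, "olfactory": 2}
_SUPRA_TOPIC = 3


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic corpus and narrative generator."""

    # corpus
    vocab_size: int = 120
    n_topics: int = 8
    synonym_pairs_per_topic: int = 2
    n_ngrams: int = 4000
    topic_leak: float = 0.05
    zipf_exponent: float = 1.0
    col_size: int = 48
    # experiment
    n_participants: int = 80
    condition_counts: Mapping[str, int] = field(
        default_factory=lambda: {c: 20 for c in CONDITIONS}
    )
    cues_per_participant: int = 15
    tokens_per_narrative: float = 40.0
    retrieval_success: float = 798 / 1200  # narratives per presented cue
    # condition structure
    effect_size: float = 0.5
    condition_effects: Mapping[str, float] | None = None
    multimodal_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    supra_weight: float = 0.0
    word_class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )

    def __post_init__(self) -> None:
        if self.n_topics * 2 > self.vocab_size:
            raise ConfigError(
                f"n_topics={self.n_topics} exceeds vocab_size/2={self.vocab_size // 2}"
            )
        if self.n_topics <= _SUPRA_TOPIC:
            raise ConfigError(f"need at least {_SUPRA_TOPIC + 1} topics")
        if sum(self.condition_counts.values()) != self.n_participants:
            raise ConfigError("condition counts must sum to n_participants")
        if set(self.condition_counts) != set(CONDITIONS):
            raise ConfigError(f"condition_counts must cover {CONDITIONS}")
        if not np.isclose(sum(self.multimodal_weights), 1.0, atol=1e-9):
            raise ConfigError("multimodal_weights must sum to 1")
        if not 0.0 <= self.supra_weight <= 1.0:
            raise ConfigError("supra_weight must be in [0, 1]")
        if not 0.0 <= self.topic_leak <= 1.0:
            raise ConfigError("topic_leak must be in [0, 1]")
        if not 0.0 < self.retrieval_success <= 1.0:
            raise ConfigError("retrieval_success must be in (0, 1]")
        props = self.word_class_proportions
        if set(props) - set(WORD_CLASSES):
            raise ConfigError("unknown word classes in proportions")
        if not np.isclose(sum(props.values()), 1.0, atol=1e-9):
            raise ConfigError("word_class_proportions must sum to 1")
        effects = dict(self.condition_effects or {})
        if set(effects) - set(UNIMODAL_CONDITIONS):
            raise ConfigError("condition_effects keys must be unimodal conditions")
        for e in [self.effect_size, *effects.values()]:
            if not 0.0 <= e <= 1.0:
                raise ConfigError("effect sizes must be in [0, 1]")

    def effect_of(self, condition: str) -> float:
        if self.condition_effects and condition in self.condition_effects:
            return float(self.condition_effects[condition])
        return self.effect_size


class _TopicModel:
    """Deterministic word/topic structure shared by corpus and narratives."""

    def __init__(self, config: GeneratorConfig):
        self.config = config
        t, v = config.n_topics, config.vocab_size
        base, extra = divmod(v, t)
        sizes = [base + (1 if i < extra else 0) for i in range(t)]
        self.topic_words: list[list[str]] = []
        w = 0
        for topic, size in enumerate(sizes):
            self.topic_words.append([f"t{topic}w{w + i:04d}" for i in range(size)])
            w += size
        self.words = [word for ws in self.topic_words for word in ws]
        self.topic_of_word = {
            word: topic for topic, ws in enumerate(self.topic_words) for word in ws
        }
        # Zipf-like within-topic emission; synonym-pair members share a weight.
        self.topic_cdfs: list[np.ndarray] = []
        self.topic_probs: list[np.ndarray] = []
        for topic, size in enumerate(sizes):
            weights = 1.0 / np.arange(1, size + 1) ** config.zipf_exponent
            for p in range(config.synonym_pairs_per_topic):
                hi, lo = 2 * p, 2 * p + 1
                if lo < size:
                    weights[lo] = weights[hi]
            probs = weights / weights.sum()
            self.topic_probs.append(probs)
            self.topic_cdfs.append(np.cumsum(probs))
        self.word_index = {word: i for i, word in enumerate(self.words)}
        # global emission under a uniform topic mixture, for the leak
        self.global_probs = self.mixture_word_probs(
            np.full(t, 1.0 / t)
        )
        self.global_cdf = np.cumsum(self.global_probs)

    def synonym_pairs(self) -> list[tuple[str, str]]:
        pairs = []
        for topic, ws in enumerate(self.topic_words):
            for p in range(self.config.synonym_pairs_per_topic):
                hi, lo = 2 * p, 2 * p + 1
                if lo < len(ws):
                    pairs.append((ws[hi], ws[lo]))
        return pairs

    def mixture_word_probs(self, topic_mixture: np.ndarray) -> np.ndarray:
        """Word emission probabilities under a mixture over topics."""
        probs = np.zeros(len(self.words))
        offset = 0
        for topic, tp in enumerate(self.topic_probs):
            probs[offset:offset + len(tp)] = topic_mixture[topic] * tp
            offset += len(tp)
        return probs

    def sample_words_for_topics(
        self, rng: np.random.Generator, topics: np.ndarray
    ) -> np.ndarray:
        """One word per entry of ``topics``, drawn from that topic's emission."""
        out = np.empty(len(topics), dtype=object)
        u = rng.random(len(topics))
        for topic in np.unique(topics):
            sel = topics == topic
            idx = np.searchsorted(self.topic_cdfs[topic], u[sel], side="right")
            ws = self.topic_words[topic]
            out[sel] = np.array(ws, dtype=object)[idx]
        return out

    def sample_tokens(
        self, rng: np.random.Generator, topic_mixture: np.ndarray, n: int
    ) -> np.ndarray:
        topics = rng.choice(self.config.n_topics, size=n, p=topic_mixture)
        return self.sample_words_for_topics(rng, topics)


def condition_mixtures(config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Topic mixtures per condition implied by the configuration.

    Each unimodal mixture is ``(1 - e) * uniform + e * onehot(signature)``;
    the multimodal mixture is the configured convex combination of the
    unimodal mixtures, optionally blended with a one-hot on the reserved
    supra-additive topic.
    """
    t = config.n_topics
    base = np.full(t, 1.0 / t)
    mixtures: dict[str, np.ndarray] = {}
    for cond in UNIMODAL_CONDITIONS:
        e = config.effect_of(cond)
        onehot = np.zeros(t)
        onehot[_SIGNATURE_TOPICS[cond]] = 1.0
        mixtures[cond] = (1.0 - e) * base + e * onehot
    w = np.asarray(config.multimodal_weights, dtype=float)
    multi = sum(wi * mixtures[c] for wi, c in zip(w, UNIMODAL_CONDITIONS))
    if config.supra_weight > 0:
        supra = np.zeros(t)
        supra[_SUPRA_TOPIC] = 1.0
        multi = (1.0 - config.supra_weight) * multi + config.supra_weight * supra
    mixtures["multimodal"] = multi
    return mixtures


@dataclass
class SyntheticCorpus:
    """A generated 5-gram corpus with its planted structure."""

    records: list[tuple[tuple[str, ...], int]]
    synonym_pairs: list[tuple[str, str]]
    vocabulary: Vocabulary
    topic_of_word: dict[str, int]
    seed: int


def generate_corpus(config: GeneratorConfig, seed: int) -> SyntheticCorpus:
    """Draw topic-pure 5-grams (with a small cross-topic leak).

    Each record samples one topic and five words from that topic's emission;
    every token independently "leaks" to the global distribution with
    probability ``topic_leak``.  With leak 0 cross-topic co-occurrence is
    exactly zero.  Output is fully determined by the seed.
    """
    rng = np.random.default_rng(seed)
    tm = _TopicModel(config)
    n = config.n_ngrams
    record_topics = rng.integers(config.n_topics, size=n)
    token_topics = np.repeat(record_topics, 5)
    leak = rng.random(5 * n) < config.topic_leak
    if leak.any():
        u = rng.random(int(leak.sum()))
        idx = np.searchsorted(tm.global_cdf, u, side="right")
        global_words = np.array(tm.words, dtype=object)[idx]
    words = tm.sample_words_for_topics(rng, token_topics)
    if leak.any():
        words[leak] = global_words
    records = [
        (tuple(words[5 * i:5 * i + 5]), 1) for i in range(n)
    ]
    frequencies = Counter(words)
    vocab = Vocabulary.from_frequencies(
        frequencies, row_size=None, col_size=config.col_size
    )
    return SyntheticCorpus(
        records=records,
        synonym_pairs=tm.synonym_pairs(),
        vocabulary=vocab,
        topic_of_word=dict(tm.topic_of_word),
        seed=seed,
    )


def generate_narratives(
    config: GeneratorConfig, seed: int
) -> tuple[pd.DataFrame, WordClassLexicon, dict]:
    """Condition-labelled narratives, a word-class lexicon, and ground truth.

    Participants are assigned to conditions in the fixed order of
    ``CONDITIONS``; each presented cue yields a narrative with probability
    ``retrieval_success``; narrative length is Poisson around
    ``tokens_per_narrative`` (at least 3 tokens) and every narrative ends in
    a full stop so the interpunction class occurs.  Ground truth records the
    mixtures and the multimodal rule so recovery can be scored.
    """
    rng = np.random.default_rng(seed)
    tm = _TopicModel(config)
    mixtures = condition_mixtures(config)
    rows = []
    pid = 0
    for cond in CONDITIONS:
        for _ in range(config.condition_counts[cond]):
            participant = f"p{pid:03d}"
            pid += 1
            for cue in range(config.cues_per_participant):
                if rng.random() >= config.retrieval_success:
                    continue  # no event retrieved for this cue
                n_tok = max(3, int(rng.poisson(config.tokens_per_narrative)))
                tokens = tm.sample_tokens(rng, mixtures[cond], n_tok)
                rows.append((
                    participant, cond, f"cue{cue:02d}", " ".join(tokens) + " .",
                ))
    frame = pd.DataFrame(
        rows, columns=["participant_id", "condition", "cue_id", "text"]
    )
    class_names = list(config.word_class_proportions)
    class_probs = np.array([config.word_class_proportions[c] for c in class_names])
    assigned = rng.choice(class_names, size=len(tm.words), p=class_probs)
    mapping = dict(zip(tm.words, (str(c) for c in assigned)))
    mapping["."] = "interpunction"
    lexicon = WordClassLexicon(mapping)
    ground_truth = {
        "seed": int(seed),
        "signature_topics": dict(_SIGNATURE_TOPICS),
        "supra_topic": _SUPRA_TOPIC,
        "condition_mixtures": {c: mixtures[c].tolist() for c in CONDITIONS},
        "multimodal_weights": list(config.multimodal_weights),
        "supra_weight": config.supra_weight,
        "effects": {c: config.effect_of(c) for c in UNIMODAL_CONDITIONS},
        "topic_of_word": {w: int(t) for w, t in tm.topic_of_word.items()},
    }
    return frame, lexicon, ground_truth


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the generating truth."""

    corpus: SyntheticCorpus
    narratives: pd.DataFrame
    lexicon: WordClassLexicon
    ground_truth: dict
    paths: dict[str, Path] = field(default_factory=dict)


def generate_bundle(
    config: GeneratorConfig, seed: int, outdir: Path | str | None = None
) -> SyntheticBundle:
    """Generate corpus + narratives; optionally write the four input files.

    Corpus and narratives use seeds derived from ``seed`` so the two streams
    are independent but jointly reproducible.
    """
    root = np.random.default_rng(seed)
    corpus_seed, narr_seed = (int(s) for s in root.integers(0, 2**31 - 1, 2))
    corpus = generate_corpus(config, corpus_seed)
    narratives, lexicon, truth = generate_narratives(config, narr_seed)
    truth["bundle_seed"] = int(seed)
    bundle = SyntheticBundle(corpus, narratives, lexicon, truth)
    if outdir is not None:
        from . import io as mio  # local import to avoid a cycle

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ngrams": outdir / "ngrams.tsv",
            "synonyms": outdir / "synonyms.tsv",
            "narratives": outdir / "narratives.csv",
            "lexicon": outdir / "lexicon.tsv",
            "ground_truth": outdir / "ground_truth.json",
        }
        mio.write_ngrams(corpus.records, paths["ngrams"])
        mio.write_synonyms(corpus.synonym_pairs, paths["synonyms"])
        mio.write_narratives(narratives, paths["narratives"])
        mio.write_lexicon(lexicon, paths["lexicon"])
        paths["ground_truth"].write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        bundle.paths = paths
    return bundle


def _simulate_representations(
    tm: _TopicModel,
    space,
    mixture: np.ndarray,
    n_participants: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Representations of simulated participants under one topic mixture."""
    index = space._index
    reps = np.empty((n_participants, space.k))
    for i in range(n_participants):
        total = np.zeros(space.k)
        for _ in range(config.cues_per_participant):
            if rng.random() >= config.retrieval_success:
                continue
            n_tok = max(3, int(rng.poisson(config.tokens_per_narrative)))
            tokens = tm.sample_tokens(rng, mixture, n_tok)
            idx = [index[t] for t in tokens if t in index]
            if idx:
                total += space.vectors[np.asarray(idx)].sum(axis=0)
        norm = np.linalg.norm(total)
        reps[i] = total / norm if norm > 0 else 0.0
    return reps


def calibrate_effect_size(
    config: GeneratorConfig,
    space,
    target_d: float = 0.8,
    *,
    seed: int,
    grid: Sequence[float] = (0.01, 0.02, 0.04, 0.08, 0.15),
    n_per_group: int = 400,
) -> float:
    """Effect-size setting that plants a population Cohen's d on the signal axis.

    The signal axis is the (deterministic) direction between the expected
    token vector of a fully signature-concentrated condition and the base
    mixture, in the supplied semantic space.  For each candidate effect size
    the separation d between simulated signal-condition and base-condition
    participants, projected on that axis, is estimated; the returned value
    interpolates the grid to hit ``target_d``.
    """
    rng = np.random.default_rng(seed)
    tm = _TopicModel(config)
    t = config.n_topics
    base = np.full(t, 1.0 / t)
    onehot = np.zeros(t)
    onehot[_SIGNATURE_TOPICS["visual"]] = 1.0
    in_space = np.array([w in space._index for w in tm.words])
    word_vecs = np.zeros((len(tm.words), space.k))
    for i, w in enumerate(tm.words):
        if in_space[i]:
            word_vecs[i] = space.vector(w)

    def expected_vector(mixture: np.ndarray) -> np.ndarray:
        probs = tm.mixture_word_probs(mixture)
        return probs @ word_vecs

    axis = expected_vector(onehot) - expected_vector(base)
    axis /= np.linalg.norm(axis)

    base_reps = _simulate_representations(tm, space, base, n_per_group, config, rng)
    base_proj = base_reps @ axis
    d_values = []
    for e in grid:
        mixture = (1.0 - e) * base + e * onehot
        reps = _simulate_representations(tm, space, mixture, n_per_group, config, rng)
        proj = reps @ axis
        sd = np.sqrt((proj.var(ddof=1) + base_proj.var(ddof=1)) / 2.0)
        d_values.append((proj.mean() - base_proj.mean()) / sd)
    d_values = np.asarray(d_values)
    if target_d <= d_values[0]:
        return float(grid[0])
    if target_d >= d_values[-1]:
        return float(grid[-1])
    return float(np.interp(target_d, d_values, np.asarray(grid)))
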