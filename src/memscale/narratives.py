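"""Participant narratives and their representation in a semantic space.

Each participant retrieved autobiographical events to sensory cues (visual,
auditory, olfactory, or all three at once) and narrated them; a participant's
semantic representation is the unit-normalised sum of the semantic vectors of
every word token across all of their narratives.  Representations can be
restricted to one of 14 word classes, in which case only tokens the lexicon
assigns to that class enter the sum.
"""

from __future__ import annotations

import logging
import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .space import SemanticSpace

log = logging.getLogger(__name__)

CONDITIONS = ("multimodal", "visual", "auditory", "olfactory")
UNIMODAL_CONDITIONS = ("visual", "auditory", "olfactory")

# The 14 grammatical word classes used for per-class representations.
WORD_CLASSES = (
    "noun",
    "adjective",
    "proper_name",
    "verb",
    "adverb",
    "participle",
    "pronoun",
    "conjunction",
    "determiner",
    "counting_word",
    "particle",
    "preposition",
    "interpunction",
    "interjection",
)
UNTAGGED = "untagged"
ALL_WORDS = "all"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lower-cased word tokens; punctuation marks become separate tokens."""
    return _TOKEN_RE.findall(text.lower())


@dataclass(frozen=True)
class Narrative:
    """One narrated event: who, under which cue condition, which cue, the text."""

    participant_id: str
    condition: str
    cue_id: str
    text: str

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValidationError(
                f"condition {self.condition!r} not in {CONDITIONS}"
            )

    def tokens(self) -> list[str]:
        return tokenize(self.text)


@dataclass
class WordClassLexicon:
    """Word -> word-class map over the 14 classes; unknown words are untagged."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.mapping.values() if c not in WORD_CLASSES}
        if bad:
            raise ValidationError(f"unknown word classes in lexicon: {sorted(bad)}")

    def tag(self, token: str) -> str:
        return self.mapping.get(token, UNTAGGED)

    def __len__(self) -> int:
        return len(self.mapping)


def tag_word_classes(
    tokens: Sequence[str], lexicon: WordClassLexicon
) -> list[tuple[str, str]]:
    """Pair each token with its lexicon class (or the untagged sentinel)."""
    return [(t, lexicon.tag(t)) for t in tokens]


@dataclass
class ParticipantRepresentation:
    """Unit vector summarising one participant's narratives in one scope.

    ``vector`` is ``None`` (never a zero vector) when no in-scope, in-space
    token exists or the token vectors cancel exactly.
    """

    participant_id: str
    condition: str
    scope: str  # "all" or one of WORD_CLASSES
    vector: np.ndarray | None
    n_tokens_used: int
    n_tokens_oov: int
    n_tokens_out_of_scope: int = 0

    @property
    def present(self) -> bool:
        return self.vector is not None


def aggregate_participant(
    narratives: Sequence[Narrative],
    space: SemanticSpace,
    scope: str = ALL_WORDS,
    lexicon: WordClassLexicon | None = None,
) -> ParticipantRepresentation:
    """Sum the space vectors of every in-scope token and normalise to length one.

    Token occurrences are weighted equally, so repeated words count
    repeatedly; token and narrative order are irrelevant.  Tokens missing
    from the space are tallied as out-of-vocabulary; tokens outside the
    requested word-class scope are tallied separately.
    """
    if not narratives:
        raise ValidationError("no narratives supplied")
    pids = {n.participant_id for n in narratives}
    conds = {n.condition for n in narratives}
    if len(pids) != 1 or len(conds) != 1:
        raise ValidationError(
            f"narratives must share one participant and condition, got {pids}/{conds}"
        )
    if scope != ALL_WORDS and scope not in WORD_CLASSES:
        raise ValidationError(f"unknown scope {scope!r}")
    if scope != ALL_WORDS and lexicon is None:
        raise ValidationError("a lexicon is required for word-class scopes")

    index = space._index
    idx: list[int] = []
    oov = out_of_scope = 0
    for narrative in narratives:
        for token in narrative.tokens():
            if scope != ALL_WORDS and lexicon.tag(token) != scope:
                out_of_scope += 1
                continue
            i = index.get(token)
            if i is None:
                oov += 1
            else:
                idx.append(i)
    if idx:
        total = space.vectors[np.asarray(idx)].sum(axis=0)
        norm = float(np.linalg.norm(total))
    else:
        total, norm = None, 0.0
    vector = total / norm if norm > 1e-12 else None
    if vector is None:
        log.debug(
            "participant %s scope %s: no usable tokens (oov=%d, out_of_scope=%d)",
            next(iter(pids)), scope, oov, out_of_scope,
        )
    return ParticipantRepresentation(
        participant_id=next(iter(pids)),
        condition=next(iter(conds)),
        scope=scope,
        vector=vector,
        n_tokens_used=len(idx),
        n_tokens_oov=oov,
        n_tokens_out_of_scope=out_of_scope,
    )


@dataclass
class RepresentationSet:
    """Representations for every participant in one scope, as a matrix.

    ``present`` marks participants with a usable representation; rows of
    ``matrix`` for absent participants are zero-filled placeholders and must
    not be interpreted as vectors.
    """

    scope: str
    participant_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    matrix: np.ndarray  # (n_participants, k)
    present: np.ndarray  # bool mask
    n_tokens_used: np.ndarray = field(default=None)
    n_tokens_oov: np.ndarray = field(default=None)


def narratives_from_frame(frame: pd.DataFrame) -> list[Narrative]:
    """Convert a ``participant_id, condition, cue_id, text`` table to records."""
    required = {"participant_id", "condition", "cue_id", "text"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"narrative table is missing columns: {sorted(missing)}")
    return [
        Narrative(str(r.participant_id), str(r.condition), str(r.cue_id), str(r.text))
        for r in frame.itertuples(index=False)
    ]


def build_representations(
    narratives: Sequence[Narrative] | pd.DataFrame,
    space: SemanticSpace,
    lexicon: WordClassLexicon | None = None,
    scopes: Sequence[str] = (ALL_WORDS,),
) -> dict[str, RepresentationSet]:
    """Aggregate every participant in every requested scope.

    Participant order follows first appearance in the input, which keeps the
    whole pipeline deterministic for a fixed input file.
    """
    if isinstance(narratives, pd.DataFrame):
        narratives = narratives_from_frame(narratives)
    by_participant: dict[str, list[Narrative]] = {}
    for n in narratives:
        by_participant.setdefault(n.participant_id, []).append(n)
    pids = tuple(by_participant)
    conditions = tuple(by_participant[p][0].condition for p in pids)
    out: dict[str, RepresentationSet] = {}
    for scope in scopes:
        reps = [
            aggregate_participant(by_participant[p], space, scope, lexicon)
            for p in pids
        ]
        matrix = np.zeros((len(pids), space.k))
        present = np.zeros(len(pids), dtype=bool)
        for i, rep in enumerate(reps):
            if rep.present:
                matrix[i] = rep.vector
                present[i] = True
        out[scope] = RepresentationSet(
            scope=scope,
            participant_ids=pids,
            conditions=conditions,
            matrix=matrix,
            present=present,
            n_tokens_used=np.array([r.n_tokens_used for r in reps]),
            n_tokens_oov=np.array([r.n_tokens_oov for r in reps]),
        )
    return out
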