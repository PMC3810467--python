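"""Readers and writers for the pipeline's tabular interchange files.

All files are UTF-8 text: n-grams and lexica are tab-separated, narratives
are CSV (or TSV when the file ends in ``.tsv``), and spaces/scales are
tab-separated with full float precision.  Readers are strict by default —
malformed lines raise :class:`~memscale.errors.ParseError` with the 1-based
line number — and tolerate both LF and CRLF endings.  ``write . read`` is
the identity on canonical records.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .narratives import WordClassLexicon
from .scales import ScaleMatrix, z_transform
from .space import NGRAM_ORDER, SemanticSpace

log = logging.getLogger(__name__)

__all__ = [
    "read_ngrams", "write_ngrams",
    "read_synonyms", "write_synonyms",
    "read_lexicon", "write_lexicon",
    "read_narratives", "write_narratives",
    "read_space", "write_space",
    "read_scales", "write_scales",
]

_FLOAT = "%.17g"


def _lines(path: Path | str):
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, raw in enumerate(fh, start=1):
            yield lineno, raw.rstrip("\r\n")


def read_ngrams(
    path: Path | str, strict: bool = True
) -> list[tuple[tuple[str, ...], int]]:
    """Read 6-column ``w1..w5<TAB>count`` records."""
    records = []
    for lineno, line in _lines(path):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != NGRAM_ORDER + 1:
            if strict:
                raise ParseError(
                    f"expected {NGRAM_ORDER + 1} tab-separated fields, got {len(parts)}",
                    path=path, line=lineno,
                )
            log.warning("%s:%d: skipping malformed n-gram line", path, lineno)
            continue
        try:
            count = int(parts[-1])
        except ValueError:
            raise ParseError(f"count is not an integer: {parts[-1]!r}",
                             path=path, line=lineno) from None
        if count < 1:
            raise ParseError(f"count must be >= 1, got {count}", path=path, line=lineno)
        records.append((tuple(parts[:NGRAM_ORDER]), count))
    return records


def write_ngrams(records: Iterable[tuple[Sequence[str], int]], path: Path | str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for tokens, count in records:
            fh.write("\t".join(tokens) + f"\t{count}\n")


def read_synonyms(path: Path | str, strict: bool = True) -> list[tuple[str, str]]:
    """Read two-words-per-line synonym pairs (tab-separated)."""
    pairs = []
    for lineno, line in _lines(path):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not all(parts):
            if strict:
                raise ParseError("expected two tab-separated words",
                                 path=path, line=lineno)
            log.warning("%s:%d: skipping malformed synonym line", path, lineno)
            continue
        pairs.append((parts[0], parts[1]))
    return pairs


def write_synonyms(pairs: Iterable[tuple[str, str]], path: Path | str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_lexicon(path: Path | str, strict: bool = True) -> WordClassLexicon:
    """Read a ``word<TAB>class`` lexicon."""
    mapping: dict[str, str] = {}
    for lineno, line in _lines(path):
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2 or not all(parts):
            if strict:
                raise ParseError("expected word<TAB>class", path=path, line=lineno)
            log.warning("%s:%d: skipping malformed lexicon line", path, lineno)
            continue
        mapping[parts[0]] = parts[1]
    try:
        return WordClassLexicon(mapping)
    except Exception as exc:
        raise ParseError(str(exc), path=path) from exc


def write_lexicon(lexicon: WordClassLexicon, path: Path | str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for word in sorted(lexicon.mapping):
            fh.write(f"{word}\t{lexicon.mapping[word]}\n")


_NARRATIVE_COLUMNS = ["participant_id", "condition", "cue_id", "text"]


def _delimiter_for(path: Path | str) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def read_narratives(path: Path | str, strict: bool = True) -> pd.DataFrame:
    """Read the narrative table ``participant_id, condition, cue_id, text``."""
    delim = _delimiter_for(path)
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty narrative file", path=path, line=1) from None
        if [h.strip() for h in header] != _NARRATIVE_COLUMNS:
            raise ParseError(
                f"expected header {_NARRATIVE_COLUMNS}, got {header}", path=path, line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_NARRATIVE_COLUMNS):
                if strict:
                    raise ParseError(
                        f"expected {len(_NARRATIVE_COLUMNS)} fields, got {len(row)}",
                        path=path, line=lineno,
                    )
                log.warning("%s:%d: skipping malformed narrative row", path, lineno)
                continue
            rows.append(row)
    return pd.DataFrame(rows, columns=_NARRATIVE_COLUMNS)


def write_narratives(frame: pd.DataFrame, path: Path | str) -> None:
    delim = _delimiter_for(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(_NARRATIVE_COLUMNS)
        for row in frame[_NARRATIVE_COLUMNS].itertuples(index=False):
            writer.writerow(list(row))


def write_space(space: SemanticSpace, path: Path | str) -> None:
    """Serialise a space as ``#k=<k>`` then ``word<TAB>v1..vk`` lines."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#k={space.k}\n")
        for word, vec in zip(space.words, space.vectors):
            coords = "\t".join(_FLOAT % v for v in vec)
            fh.write(f"{word}\t{coords}\n")


def read_space(path: Path | str) -> SemanticSpace:
    lines = list(_lines(path))
    if not lines or not lines[0][1].startswith("#k="):
        raise ParseError("space file must start with a '#k=<k>' header",
                         path=path, line=1)
    try:
        k = int(lines[0][1][3:])
    except ValueError:
        raise ParseError("malformed '#k=' header", path=path, line=1) from None
    words, vectors = [], []
    for lineno, line in lines[1:]:
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != k + 1:
            raise ParseError(f"expected word + {k} coordinates", path=path, line=lineno)
        words.append(parts[0])
        try:
            vectors.append([float(v) for v in parts[1:]])
        except ValueError:
            raise ParseError("non-numeric coordinate", path=path, line=lineno) from None
    arr = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(arr, axis=1, keepdims=True)
    return SemanticSpace(words=tuple(words), vectors=arr / norms, k=k)


_SCALE_COLUMNS = ["participant_id", "condition", "scale_target", "value", "z_value", "scope"]


def write_scales(matrix: ScaleMatrix, path: Path | str, scope: str = "combined") -> None:
    """Long-format TSV: one row per participant x scale target."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_SCALE_COLUMNS) + "\n")
        for target in matrix.values.columns:
            values = matrix.scale(target)
            z = z_transform(values)
            for pid, cond, v, zv in zip(
                matrix.participant_ids, matrix.conditions, values, z
            ):
                fh.write(
                    f"{pid}\t{cond}\t{target}\t{_FLOAT % v}\t{_FLOAT % zv}\t{scope}\n"
                )


def read_scales(path: Path | str) -> ScaleMatrix:
    frame = pd.read_csv(path, sep="\t")
    missing = set(_SCALE_COLUMNS) - set(frame.columns)
    if missing:
        raise ParseError(f"scale file missing columns: {sorted(missing)}", path=path)
    wide = frame.pivot(index="participant_id", columns="scale_target", values="value")
    conditions = frame.drop_duplicates("participant_id").set_index("participant_id")[
        "condition"
    ]
    order = list(dict.fromkeys(frame["participant_id"]))
    wide = wide.loc[order]
    return ScaleMatrix(
        participant_ids=tuple(order),
        conditions=tuple(conditions.loc[order]),
        values=wide,
    )
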