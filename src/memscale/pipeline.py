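"""End-to-end pipeline: corpus -> space -> representations -> scales -> tests.

:func:`run_pipeline` sequences the whole analysis from the four input files,
writes every stage output plus a run manifest into the output directory, and
fails fast with the offending stage named.  All randomness (synonym test,
Monte-Carlo overlap) flows from the single configured seed, so reruns with
identical inputs and configuration reproduce all numeric outputs exactly.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io as mio
from .errors import ConfigError, MemscaleError
from .hypotheses import (
    all_projection_pairs,
    comparison_tables,
    dominance_ranking,
    triangular_test,
    unimodal_projection_pairs,
)
from .narratives import ALL_WORDS, WORD_CLASSES, build_representations
from .scales import build_scale_matrix, code_conditions, evaluate_scale
from .space import (
    Vocabulary,
    build_space,
    count_cooccurrences,
    log_normalize,
    select_dimensionality,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and knobs for one full analysis run."""

    ngrams: Path
    narratives: Path
    lexicon: Path
    outdir: Path
    synonyms: Path | None = None
    row_size: int | None = None  # default: whole corpus vocabulary
    col_size: int | None = None  # default: min(vocabulary, 2000)
    k: int | None = None
    k_grid: tuple[int, ...] | None = None  # requires a synonym file
    n_random: int = 1000
    per_class: bool = True
    projections: str = "unimodal"  # "unimodal" (3 pairs) or "all" (6 pairs)
    mc_samples: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if (self.k is None) == (self.k_grid is None):
            raise ConfigError("exactly one of k / k_grid must be set")
        if self.k_grid is not None and self.synonyms is None:
            raise ConfigError("dimension selection (k_grid) requires a synonym file")
        if self.projections not in ("unimodal", "all"):
            raise ConfigError("projections must be 'unimodal' or 'all'")
        for name in ("ngrams", "narratives", "lexicon"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise ConfigError(f"{name} file does not exist: {p}")
        if self.synonyms is not None and not Path(self.synonyms).exists():
            raise ConfigError(f"synonyms file does not exist: {self.synonyms}")


@dataclass
class RunManifest:
    """Record of one pipeline run: config, version, row counts, timing."""

    config: dict
    version: str
    counts: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path: Path) -> None:
        tmp = path.with_suffix(".tmp")
        tmp.write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        tmp.replace(path)  # atomic on POSIX


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MemscaleError):
                raise MemscaleError(f"stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the complete analysis and write all outputs under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        version=__version__,
        started=time.time(),
    )

    with _stage("build-space"):
        records = mio.read_ngrams(config.ngrams)
        freqs: dict[str, int] = {}
        for tokens, count in records:
            for t in tokens:
                freqs[t] = freqs.get(t, 0) + count
        vocab = Vocabulary.from_frequencies(
            freqs,
            row_size=config.row_size,
            col_size=config.col_size if config.col_size is not None
            else min(len(freqs), 2000),
        )
        matrix = log_normalize(count_cooccurrences(records, vocab))
        if config.k_grid is not None:
            pairs = mio.read_synonyms(config.synonyms)
            selection = select_dimensionality(
                matrix, pairs, config.k_grid,
                n_random=config.n_random, seed=config.seed,
            )
            k = selection.chosen_k
            (outdir / "synonym_scores.json").write_text(
                json.dumps(
                    {
                        "scores": {str(kk): v for kk, v in selection.scores.items()},
                        "chosen_k": k,
                        "n_random": selection.n_random,
                        "seed": selection.seed,
                    },
                    indent=2, sort_keys=True,
                ) + "\n",
                encoding="utf-8",
            )
        else:
            k = config.k
        space = build_space(matrix, k)
        mio.write_space(space, outdir / "space.tsv")
        manifest.counts["ngram_records"] = len(records)
        manifest.counts["space_words"] = len(space)
        manifest.counts["space_dropped_words"] = len(space.dropped_words)
        manifest.counts["k"] = k

    with _stage("represent"):
        narr = mio.read_narratives(config.narratives)
        lexicon = mio.read_lexicon(config.lexicon)
        scopes = (ALL_WORDS, *WORD_CLASSES) if config.per_class else (ALL_WORDS,)
        reps = build_representations(narr, space, lexicon, scopes=scopes)
        base = reps[ALL_WORDS]
        manifest.counts["narratives"] = len(narr)
        manifest.counts["participants"] = len(base.participant_ids)
        manifest.counts["tokens_used"] = int(base.n_tokens_used.sum())
        manifest.counts["tokens_oov"] = int(base.n_tokens_oov.sum())

    with _stage("scales"):
        scale_matrix = build_scale_matrix(reps, per_class=config.per_class)
        mio.write_scales(
            scale_matrix, outdir / "scales.tsv",
            scope="combined" if config.per_class else ALL_WORDS,
        )
        validity = {}
        for target in scale_matrix.values.columns:
            codes = code_conditions(scale_matrix.conditions, target)
            r, p = evaluate_scale(scale_matrix.scale(target), codes)
            validity[target] = {"r": r, "p_one_sided": p}
        manifest.counts["scale_columns"] = int(scale_matrix.values.shape[1])

    with _stage("test"):
        table = comparison_tables(scale_matrix)
        table.p_values.to_csv(outdir / "p_values.tsv", sep="\t", float_format="%.6g")
        table.effect_sizes.to_csv(
            outdir / "effect_sizes.tsv", sep="\t", float_format="%.6g"
        )
        pairs = (
            unimodal_projection_pairs()
            if config.projections == "unimodal"
            else all_projection_pairs()
        )
        triangles = triangular_test(
            scale_matrix, pairs, mc_samples=config.mc_samples, seed=config.seed
        )
        results = {
            "seed": config.seed,
            "scale_validity": validity,
            "p_values": {r: _row_dict(table.p_values, r) for r in table.p_values.index},
            "effect_sizes": {
                r: _row_dict(table.effect_sizes, r) for r in table.effect_sizes.index
            },
            "dominance_ranking": list(dominance_ranking(table)),
            "triangle_tests": [
                {
                    "projection": list(t.projection),
                    "means": {c: m.tolist() for c, m in t.means.items()},
                    "radii": {c: float(r) for c, r in t.radii.items()},
                    "mean_inside": bool(t.mean_inside),
                    "mean_position": t.mean_position,
                    "circle_triangle_overlap": bool(t.circle_triangle_overlap),
                    "overlap_fraction": float(t.overlap_fraction),
                    "mc_samples": t.mc_samples,
                    "seed": t.seed,
                }
                for t in triangles
            ],
        }
        (outdir / "results.json").write_text(
            json.dumps(results, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest.counts["triangle_projections"] = len(triangles)

    manifest.finished = time.time()
    manifest.write(outdir / "manifest.json")
    return manifest


def _row_dict(frame, row) -> dict:
    return {
        c: (None if np.isnan(v) else float(v)) for c, v in frame.loc[row].items()
    }
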