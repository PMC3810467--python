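"""Simulation studies that check the pipeline's statistical behaviour.

Because the original narrative data and the terabyte-scale corpus behind the
published analysis are not redistributable, the pipeline is validated on
synthetic data with known structure: calibration of the synonym test,
type-I error of the scale validity test under a null generator, power to
detect a planted condition signal, recovery of multimodal mixture weights by
the dominance ranking, and recovery of convex versus supra-additive
multimodal mixing by the triangle test.

Replicate studies run at a reduced scale — a 96-word / 3000-record corpus
and a 16-dimensional space, with 80 participants, 10 cues each and ~30
tokens per narrative — chosen so that a thousand replicates complete in
minutes while every replicate still runs the genuine pipeline path
(token sampling, aggregation, leave-one-subject-out regression, tests).
Replicates use the fast all-words scale variant; the synthetic word classes
carry no differential signal by construction, so the per-class-then-combine
stage adds only noise and runtime there (it is exercised separately by the
end-to-end pipeline run).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .hypotheses import comparison_tables, dominance_ranking, triangular_test
from .narratives import ALL_WORDS, CONDITIONS, build_representations
from .scales import ScaleMatrix, build_scale_matrix, code_conditions, evaluate_scale
from .simulate import (
    GeneratorConfig,
    calibrate_effect_size,
    generate_corpus,
    generate_narratives,
)
from .space import SemanticSpace, build_space, count_cooccurrences, log_normalize

__all__ = [
    "REDUCED_CONFIG",
    "STUDY_K",
    "study_space",
    "replicate_scale_matrix",
    "synonym_random_calibration",
    "planted_synonym_study",
    "type_i_error_study",
    "differential_power_study",
    "dominance_recovery_study",
    "triangle_recovery_study",
]

# Reduced-scale study conditions (see module docstring).
REDUCED_CONFIG = GeneratorConfig(
    vocab_size=96,
    n_topics=8,
    n_ngrams=3000,
    cues_per_participant=10,
    tokens_per_narrative=30.0,
)
STUDY_K = 16


def study_space(
    config: GeneratorConfig = REDUCED_CONFIG, *, seed: int, k: int = STUDY_K
):
    """Build one corpus and space shared by all replicates of a study."""
    corpus = generate_corpus(config, seed)
    matrix = log_normalize(count_cooccurrences(corpus.records, corpus.vocabulary))
    rank = min(matrix.counts.shape)
    space = build_space(matrix, min(k, rank))
    return corpus, space


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def replicate_scale_matrix(
    config: GeneratorConfig,
    space: SemanticSpace,
    rep_seed: int,
    targets=CONDITIONS,
) -> tuple[ScaleMatrix, np.ndarray]:
    """One replicate: narratives -> representations -> all-words LOO scales."""
    narr, _, _ = generate_narratives(config, rep_seed)
    reps = build_representations(narr, space, scopes=(ALL_WORDS,))
    sm = build_scale_matrix(reps, per_class=False, targets=targets)
    return sm, reps[ALL_WORDS].matrix


def synonym_random_calibration(
    n_replicates: int = 200,
    n_pairs: int = 30,
    n_random: int = 500,
    *,
    seed: int,
    config: GeneratorConfig = REDUCED_CONFIG,
    k: int = STUDY_K,
) -> dict:
    """Synonym-test scores when the "synonyms" are uniformly random pairs.

    The median score should sit near 50 (chance): each replicate scores
    ``n_pairs`` random word pairs and the summary is the median of the
    replicate medians.
    """
    from .space import synonym_test

    _, space = study_space(config, seed=seed, k=k)
    seeds = _spawn_seeds(seed, n_replicates)
    rng = np.random.default_rng(seed + 1)
    n = len(space)
    medians = []
    for s in seeds:
        i = rng.integers(n, size=n_pairs)
        j = rng.integers(n, size=n_pairs)
        j = np.where(i == j, (j + 1) % n, j)
        pairs = [(space.words[a], space.words[b]) for a, b in zip(i, j)]
        medians.append(synonym_test(space, pairs, n_random, seed=int(s)))
    medians = np.asarray(medians)
    return {
        "median_of_medians": float(np.median(medians)),
        "replicate_medians": medians,
        "n_replicates": n_replicates,
    }


def planted_synonym_study(
    *,
    seed: int,
    config: GeneratorConfig | None = None,
    n_random: int = 1000,
) -> dict:
    """Synonym test on the default synthetic corpus with its planted pairs.

    Builds the space at the dimensionality the synonym test itself selects
    (doubling grid) and scores the planted pairs; a shuffled-pair null
    (members re-paired across topics) is scored for contrast.
    """
    from .space import select_dimensionality, synonym_test

    config = config or GeneratorConfig()
    corpus = generate_corpus(config, seed)
    matrix = log_normalize(count_cooccurrences(corpus.records, corpus.vocabulary))
    grid = [k for k in (1, 2, 4, 8, 16, 32) if k <= min(matrix.counts.shape)]
    selection = select_dimensionality(
        matrix, corpus.synonym_pairs, grid, n_random=n_random, seed=seed
    )
    space = build_space(matrix, selection.chosen_k)
    planted = synonym_test(space, corpus.synonym_pairs, n_random, seed=seed)
    rng = np.random.default_rng(seed + 1)
    firsts = [a for a, _ in corpus.synonym_pairs]
    seconds = [b for _, b in corpus.synonym_pairs]
    shuffled = list(zip(firsts, rng.permutation(seconds)))
    shuffled_score = synonym_test(space, shuffled, n_random, seed=seed)
    return {
        "planted_score": planted,
        "shuffled_score": shuffled_score,
        "chosen_k": selection.chosen_k,
        "scores_by_k": selection.scores,
    }


def type_i_error_study(
    n_replicates: int = 1000,
    alpha: float = 0.05,
    *,
    seed: int,
    config: GeneratorConfig = REDUCED_CONFIG,
    target: str = "visual",
) -> dict:
    """Rejection rate of the scale validity test under a null generator.

    Effect size 0 makes all conditions share one token distribution, so the
    one-sided test of r > 0 between codes and LOO predictions should reject
    at close to the nominal rate.
    """
    null_config = replace(config, effect_size=0.0)
    _, space = study_space(config, seed=seed)
    seeds = _spawn_seeds(seed + 1, n_replicates)
    rejections = 0
    for s in seeds:
        sm, _ = replicate_scale_matrix(null_config, space, int(s), targets=(target,))
        codes = code_conditions(sm.conditions, target)
        _, p = evaluate_scale(sm.values[target].to_numpy(), codes)
        rejections += p < alpha
    return {
        "rejection_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def visual_only_config(
    config: GeneratorConfig = REDUCED_CONFIG,
    *,
    seed: int,
    target_d: float = 0.8,
    space: SemanticSpace | None = None,
) -> GeneratorConfig:
    """Configuration planting signal in the visual condition only.

    The visual effect size is calibrated so the population separation on the
    signal axis is ``target_d``; the auditory and olfactory conditions stay
    at the base mixture, and the multimodal condition mixes only those two,
    so it carries no visual signal either.
    """
    if space is None:
        _, space = study_space(config, seed=seed)
    e = calibrate_effect_size(config, space, target_d, seed=seed + 7)
    return replace(
        config,
        condition_effects={"visual": e, "auditory": 0.0, "olfactory": 0.0},
        multimodal_weights=(0.0, 0.5, 0.5),
    )


def differential_power_study(
    n_replicates: int = 200,
    alpha: float = 0.05,
    *,
    seed: int,
    config: GeneratorConfig = REDUCED_CONFIG,
    target_d: float = 0.8,
) -> dict:
    """One-vs-rest rejection rates per scale with a visual-only planted signal.

    The visual scale should reject often (power); the other three scales have
    no planted own-condition signal.
    """
    _, space = study_space(config, seed=seed)
    study_config = visual_only_config(config, seed=seed, target_d=target_d, space=space)
    seeds = _spawn_seeds(seed + 2, n_replicates)
    rejections = {c: 0 for c in CONDITIONS}
    for s in seeds:
        sm, _ = replicate_scale_matrix(study_config, space, int(s))
        table = comparison_tables(sm)
        for c in CONDITIONS:
            rejections[c] += table.p_values.loc[c, "all_others"] < alpha
    return {
        "rejection_rates": {c: rejections[c] / n_replicates for c in CONDITIONS},
        "visual_effect_size": study_config.effect_of("visual"),
        "n_replicates": n_replicates,
        "alpha": alpha,
    }


def dominance_recovery_study(
    n_replicates: int = 100,
    weights: tuple[float, float, float] = (0.6, 0.3, 0.1),
    *,
    seed: int,
    config: GeneratorConfig = REDUCED_CONFIG,
) -> dict:
    """How often the dominance ranking recovers the multimodal mixture order.

    With weights (visual, auditory, olfactory) well separated, the ranking by
    ascending |d| to the multimodal condition should reproduce the weight
    order.
    """
    study_config = replace(config, multimodal_weights=weights)
    expected = tuple(
        c for _, c in sorted(
            zip(weights, ("visual", "auditory", "olfactory")), reverse=True
        )
    )
    _, space = study_space(config, seed=seed)
    seeds = _spawn_seeds(seed + 3, n_replicates)
    hits = 0
    for s in seeds:
        sm, _ = replicate_scale_matrix(study_config, space, int(s))
        hits += dominance_ranking(comparison_tables(sm)) == expected
    return {
        "recovery_rate": hits / n_replicates,
        "expected_order": expected,
        "n_replicates": n_replicates,
    }


def triangle_recovery_study(
    n_replicates: int = 100,
    supra_weight: float = 0.0,
    *,
    seed: int,
    config: GeneratorConfig = REDUCED_CONFIG,
    mc_samples: int = 2000,
) -> dict:
    """Rate at which the multimodal mean lies inside the unimodal triangle.

    A replicate counts as "inside" when the multimodal mean is inside (or on
    the boundary of) the triangle in *all* unimodal 2-D projections —
    containment in the spanned region is preserved by linear projection, so
    falling outside any projection refutes it.  With convex mixing the rate
    should be high; with a strong supra-additive component it should be low.
    """
    study_config = replace(
        config, multimodal_weights=(1 / 3, 1 / 3, 1 / 3), supra_weight=supra_weight
    )
    _, space = study_space(config, seed=seed)
    seeds = _spawn_seeds(seed + 4, n_replicates)
    inside = 0
    for s in seeds:
        sm, _ = replicate_scale_matrix(study_config, space, int(s))
        results = triangular_test(sm, mc_samples=mc_samples, seed=int(s))
        inside += all(t.mean_inside for t in results)
    return {
        "inside_rate": inside / n_replicates,
        "supra_weight": supra_weight,
        "n_replicates": n_replicates,
    }
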