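"""Build a semantic space from a synthetic 5-gram corpus and pick its size.

Generates a small corpus with eight planted topics, accumulates the
distance-weighted co-occurrence matrix, log-compresses it, and lets the
synonym test choose the dimensionality over a doubling grid.  Low synonym
scores mean synonym pairs rank far above random word pairs by cosine.
"""

import memscale as ms

config = ms.GeneratorConfig()  # 120 words, 8 topics, 4000 five-grams
corpus = ms.generate_corpus(config, seed=1)
matrix = ms.log_normalize(ms.count_cooccurrences(corpus.records, corpus.vocabulary))

selection = ms.select_dimensionality(
    matrix, corpus.synonym_pairs, k_grid=(1, 2, 4, 8, 16, 32), n_random=1000, seed=1
)
print("synonym-test score (%) per dimensionality, lower is better:")
for k, score in selection.scores.items():
    marker = "  <- chosen" if k == selection.chosen_k else ""
    print(f"  k={k:>3}: {score:6.2f}{marker}")

space = ms.build_space(matrix, selection.chosen_k)
a, b = corpus.synonym_pairs[0]
print(f"\nspace: {len(space)} words, {space.k} dimensions")
print(f"cosine of planted synonyms ({a}, {b}): "
      f"{ms.cosine_similarity(space, a, b):.3f}")
w1, w2 = space.words[0], space.words[-1]
print(f"cosine of unrelated words   ({w1}, {w2}): "
      f"{ms.cosine_similarity(space, w1, w2):.3f}")
print("\nA score near 0 means synonyms beat essentially all random pairs; "
      "50 would be chance.")
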