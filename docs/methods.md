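# Methods

This note documents the models, defaults, numerical choices and known
limitations of `memscale`.  It is the package's own account of what it
computes; every empirical figure quoted here is produced by the test suite
or `scripts/acceptance.py`.

## 1. Semantic space

The space is a classic log/SVD distributional model built from 5-gram
windows.

* **Counting.**  Every ordered position pair `(i, j)`, `i ≠ j`, within a
  5-gram contributes `5 − |i − j|` times the record count to the cell
  (row word at *i*, context word at *j*).  The weight map `d ↦ 5 − d`
  (4, 3, 2, 1 for distances 1–4) is the unique weakly decreasing integer
  assignment consistent with weighting adjacent words 4 and window-edge
  words 1.  All ordered pairs contribute symmetrically; no position is
  singled out as "target", which is the standard reading for this family of
  models and uses every weight.
* **Normalisation.**  `log(1 + count)`, natural base.  The base only
  rescales all cells uniformly, so cosines after a full-rank SVD are
  unaffected by the choice.
* **Projection.**  Word vectors are rows of `U S` truncated to *k*
  dimensions, then unit-normalised.  `U S` (rather than `U`) preserves the
  Euclidean geometry of the normalised matrix rows exactly at full rank;
  the test suite asserts the Gram-matrix identity to 1e-6.  Rows whose
  *k*-dimensional projection is numerically zero (norm < 1e-12) are dropped
  from the space and recorded, never normalised.
* **Dimensionality selection.**  For each candidate *k* on a doubling grid,
  every synonym pair is scored by the mid-rank percentile of its cosine
  among `n_random` seeded random pairs (sampled with replacement, self-pairs
  excluded, ties counted ½); the score is the median over pairs and the
  lowest-scoring *k* wins, ties to the smaller *k*.  The same seed (hence
  the same random pairs) is used for every *k* so scores are comparable.
  "Lowest percentile = best" is the intended reading of the test: a
  percentile near 0 means synonyms out-rank essentially all random pairs.

## 2. Participant representations

Narratives are lower-cased and split into word tokens, with punctuation
emitted as separate tokens so the "interpunction" word class is reachable.
A participant's representation is the unit-normalised sum of the space
vectors of all their tokens — per occurrence, not per type ("each word
weighted equally" is read as equal weight per token, the convention in this
model family).  Per-class representations restrict the sum to tokens the
lexicon maps to that class; untagged tokens count in the all-words scope
only.  A participant with no usable in-space token is *absent* (no vector),
never a zero vector.  Representations are invariant to token order,
narrative order, and duplication of a participant's corpus.

## 3. Semantic scales

For target condition *c*: codes are +1 (in *c*) / −1 (otherwise).  For each
participant the remaining n − 1 form a training fold; dimensions are ranked
by |Pearson r| with the codes *within the fold* (zero-variance dimensions
score 0 and sort last, ties by index), the top `⌊n/2⌋` enter an OLS fit
with intercept, and the fit is evaluated on the held-out participant.
Design choices:

* The subset size is pinned to the number of *predicted* data points
  (n = 80 → 40 dimensions), reused in every fold.
* The intercept absorbs the ±1 base rate of the unbalanced coding
  (20 vs 60).
* Singular fold designs get the minimum-norm least-squares solution
  (`numpy.linalg.lstsq`), deterministically.
* Per-class scales use the same construction within each class; participants
  lacking a class representation receive the neutral value 0 on that class's
  scale (0 is the natural neutral point since predictions straddle 0).
  The combined scale is a second leave-one-subject-out OLS whose features
  are the per-class scale values (at most 14, so no subset step).
* Two classes of degenerate inputs are excluded from the combination, with a
  logged warning: classes with fewer than four usable participants, and
  classes in which every usable participant has an identical representation
  (e.g. a one-word class).  The latter is essential, not cosmetic: the LOO
  prediction for an information-free class is the left-out-dependent
  training mean — a pure leakage artifact anti-correlated with the
  participant's own code — and combined with zero-filled absences it is
  near-collinear with the intercept on some folds, producing unbounded
  extrapolation.  A constant-scale guard catches the same pathology one
  step later.
* Scale validity is Pearson r between codes and predictions with a
  one-sided p for r > 0.  The reported z-transform divides the z-score by
  `√(n − 1)`, as specified for this analysis style; the conventional
  z-score is exposed separately (`standard_z`) for diagnostics.

## 4. Hypothesis tests

* **Differential.**  One-sided two-sample t-tests with pooled variance (the
  classical default; not Welch) and Cohen's d with (n−1)-weighted pooled SD.
  Each scale row compares its own condition against the three others pooled
  and against each other condition pairwise — always on that row's scale, so
  the table is deliberately asymmetric.  P-values are uncorrected; a Holm
  option exists for users but is off by default.
* **Dominance.**  Unimodal conditions sorted by ascending |d| between their
  own scale's condition and the multimodal condition; ties break in the
  fixed order visual, auditory, olfactory.
* **Triangular.**  Per pair of scale axes (default: the three unimodal
  pairs; all six optionally), the triangle is the convex hull of the three
  unimodal 2-D means.  The multimodal mean is classified by barycentric
  coordinates (boundary tolerance 1e-12; collinear vertices are an error).
  The 95% confidence circle uses radius `1.96·√((s²ₓ+s²ᵧ)/2)/√n` — an
  isotropic CI of the mean, which yields a circle rather than an ellipse;
  the data-spread interpretation of the circles is deliberately not the
  default.  Circle–triangle overlap is reported two ways: an exact
  segment-distance test (tolerance 1e-9 on tangency) for the binary
  verdict, and a seeded Monte-Carlo fraction of disc points inside the
  triangle (default 10⁴ samples) for the magnitude.  Containment of a point
  in the hull of three points is preserved under linear projection, so
  falling outside *any* projection refutes convex mixing; the recovery
  studies therefore call a replicate "inside" only when all projections are.

## 5. Synthetic data generator

The generator emulates the study inputs with a small topic model.

* **Corpus.**  A vocabulary (default 120 words) is partitioned into topics
  (default 8); within-topic emission is Zipf-like, with designated synonym
  pairs tied to equal probability.  Each 5-gram draws one topic and five
  words from it; each token leaks to the corpus-wide distribution with
  probability 0.05.  With zero leak, cross-topic co-occurrence is exactly
  zero.
* **Narratives.**  80 participants, 20 per condition, 15 cues each; each cue
  yields a narrative with probability 798/1200 ≈ 0.665 (the study-sized
  retrieval success rate); narrative length is Poisson with mean 40 tokens
  (minimum 3) — a plausible length for a short spoken narration — ending in
  a full stop.  Each unimodal condition's topic mixture is
  `(1 − e)·uniform + e·onehot(signature topic)`; the multimodal mixture is a
  configurable convex combination of the three unimodal mixtures, optionally
  blended (weight `supra_weight`) with a one-hot on a reserved fourth topic
  that no unimodal condition uses — the generative meaning of
  supra-additivity.  Effect size 0 makes all four conditions identical (the
  null).  The default effect size 0.5 is a deliberately strong,
  demonstration-friendly signal; studies that need a specific population
  separation calibrate it (below).
* **Lexicon.**  Every vocabulary word is assigned one of the 14 word classes
  at random with roughly natural-language proportions (nouns 23%, verbs 18%,
  …, interjections 0.5%); "." is interpunction.  Classes are independent of
  topics, so they carry no differential signal — per-class scales on
  synthetic data test plumbing and variance behaviour, not class-specific
  meaning.
* **Calibration.**  `calibrate_effect_size` finds the mixture effect that
  plants a target Cohen's d between signal-condition and base-condition
  participants *on the signal axis* — the deterministic direction between
  the expected token vectors of the concentrated and base mixtures —
  estimated by simulating participants at a grid of effects and
  interpolating.  Validation confirms the calibration is accurate (realized
  axis-d ≈ 0.79 for target 0.8).

What the generator does **not** emulate: morphology, syntax, discourse
structure, Zipfian vocabulary across topics, within-participant topical
drift, or any correlation between word class and condition.  Passing tests
therefore demonstrate the pipeline's statistical behaviour under a clean
topic-mixture world, not linguistic realism.

## 6. Validation studies and their problem sizes

Replicated studies (`memscale.validation`) run on a reduced configuration
chosen so a thousand replicates finish in minutes on one CPU while every
replicate exercises the genuine pipeline path: a 96-word, 8-topic,
3000-record corpus; a k = 16 space; 80 participants with 10 cues and ~30
tokens per narrative.  Replicates use the all-words scale variant: the
synthetic word classes are independent of the signal by construction, so
the per-class-then-combine stage adds only runtime and noise there (it is
exercised end-to-end by the pipeline reproducibility test and the unit
suite).  The space is built once per study; narratives are regenerated per
replicate from spawned sub-seeds.

## 7. Known limitations

Two statistical properties of the scale construction matter when
interpreting results, and both are measured, not hidden:

* **Cross-validation attenuation.**  The leave-one-subject-out scale
  estimates its projection direction from n − 1 noisy points, so a
  population separation d on the signal axis arrives at the scale level
  attenuated.  At n = 80 and k = 16, a planted axis-d of 0.8 yields a
  scale-level d ≈ 0.4 and one-vs-rest power ≈ 0.42 — far below the ≈ 0.92
  an oracle that knew the axis would achieve.  The effect is intrinsic: a
  pure Gaussian idealization reproduces it at every k (power 0.72/0.60/0.55/
  0.43 at k = 2/4/8/16).  Planted effects must be interpreted on the scale,
  not the axis.
* **Mild anti-conservatism of the validity test.**  The one-sided Pearson
  test of r > 0 between codes and LOO predictions assumes independent
  pairs, but LOO predictions share training data.  Under the null the
  realized size at α = 0.05 grows with k: ≈ 0.032 at k = 4, ≈ 0.057 at
  k = 8, ≈ 0.076 at k = 16 (Gaussian idealization and the generator agree
  within sampling error).  At the validation studies' k = 16 the test is
  therefore slightly liberal — its size straddles the upper edge of a
  5% ± 2% tolerance; a permutation test would fix this but is outside the
  analysis being reproduced.
* **One-vs-rest contrasts are coupled across scales.**  When one condition
  truly shifts, it sits inside every other scale's pooled "rest" group, so
  non-target one-vs-rest tests are not exactly null (measured rejection
  ≈ 0.10–0.12 at a planted visual-only d = 0.8).  Pairwise contrasts
  between unshifted conditions remain null.

Smaller practical notes: SVD sign indeterminacy is irrelevant to cosines
and is deterministic for a fixed input (same LAPACK path), which is what
the bit-reproducibility guarantee relies on; all stochastic operations take
explicit seeds and no global random state is used anywhere.
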