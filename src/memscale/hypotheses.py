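"""Hypothesis tests on the four semantic scales.

Three questions are asked of the participants-by-scales matrix:

* **Differential** — do the cue conditions produce different scale values?
  One-sided two-sample t-tests (pooled variance) compare each scale's own
  condition against the three others pooled and against each condition
  pairwise; Cohen's d quantifies each contrast.  No multiple-comparison
  correction is applied by default.
* **Visual dominance** — which unimodal condition sits closest to the
  multimodal condition?  Unimodal conditions are ranked by the absolute
  effect size between their own scale's condition and the multimodal
  condition; a smaller |d| means the two conditions are closer.
* **Triangular** — in a 2-D projection onto two scales, does the multimodal
  condition's mean fall inside the triangle spanned by the three unimodal
  condition means?  Containment of the mean and overlap between the triangle
  and the multimodal 95% confidence circle are both reported.
"""

from __future__ import annotations

import itertools
import logging
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateGeometryError, ValidationError
from .narratives import CONDITIONS, UNIMODAL_CONDITIONS
from .scales import ScaleMatrix

log = logging.getLogger(__name__)

ALL_OTHERS = "all_others"

__all__ = [
    "ConditionComparisonTable",
    "TriangleTestResult",
    "one_sided_t",
    "cohens_d",
    "comparison_tables",
    "dominance_ranking",
    "condition_mean_ci",
    "point_in_triangle",
    "triangular_test",
    "unimodal_projection_pairs",
    "all_projection_pairs",
]


def _pooled_sd(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    return float(np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    ))


def one_sided_t(x: Sequence[float], y: Sequence[float]) -> float:
    """Pooled-variance two-sample t-test, alternative mean(x) > mean(y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("both samples need at least two values")
    if _pooled_sd(x, y) == 0:
        raise ValidationError("zero pooled variance; t-test undefined")
    res = stats.ttest_ind(x, y, equal_var=True, alternative="greater")
    return float(res.pvalue)


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Standardised mean difference ``(mean(x) - mean(y)) / pooled SD``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("both samples need at least two values")
    sd = _pooled_sd(x, y)
    if sd == 0:
        raise ValidationError("zero pooled standard deviation; d undefined")
    return float((x.mean() - y.mean()) / sd)


@dataclass
class ConditionComparisonTable:
    """P-values and effect sizes for one-vs-rest and pairwise contrasts.

    Rows are scales (named by their target condition); columns are the pooled
    "all_others" contrast followed by the four conditions.  The diagonal
    (a condition against itself on its own scale) is undefined.  The grids
    are intentionally asymmetric: each row is computed on a different scale.
    """

    p_values: pd.DataFrame
    effect_sizes: pd.DataFrame

    def cell(self, scale: str, column: str) -> tuple[float, float]:
        return (
            float(self.p_values.loc[scale, column]),
            float(self.effect_sizes.loc[scale, column]),
        )


def comparison_tables(
    scales: ScaleMatrix, correction: str | None = None
) -> ConditionComparisonTable:
    """Build the full contrast tables from the participants-by-scales matrix.

    For scale row *r*: the ``all_others`` column tests condition *r* against
    the other three conditions pooled; pairwise column *c* tests condition
    *r* against condition *c*, always on scale *r*.  P-values are one-sided
    (own condition more positive) and uncorrected by default;
    ``correction="holm"`` applies a Holm step-down adjustment jointly over
    all cells.
    """
    if correction not in (None, "holm"):
        raise ValidationError(f"unknown correction {correction!r}")
    present = set(scales.conditions)
    missing = set(CONDITIONS) - present
    if missing:
        raise ValidationError(f"conditions missing from data: {sorted(missing)}")
    missing_cols = set(CONDITIONS) - set(scales.values.columns)
    if missing_cols:
        raise ValidationError(f"scale columns missing: {sorted(missing_cols)}")
    columns = [ALL_OTHERS, *CONDITIONS]
    p = pd.DataFrame(np.nan, index=list(CONDITIONS), columns=columns)
    d = pd.DataFrame(np.nan, index=list(CONDITIONS), columns=columns)
    for row in CONDITIONS:
        values = scales.scale(row)
        own = values[scales.condition_mask(row)]
        rest = values[~scales.condition_mask(row)]
        p.loc[row, ALL_OTHERS] = one_sided_t(own, rest)
        d.loc[row, ALL_OTHERS] = cohens_d(own, rest)
        for col in CONDITIONS:
            if col == row:
                continue
            other = values[scales.condition_mask(col)]
            p.loc[row, col] = one_sided_t(own, other)
            d.loc[row, col] = cohens_d(own, other)
    if correction == "holm":
        from statsmodels.stats.multitest import multipletests

        flat = p.to_numpy().ravel()
        mask = ~np.isnan(flat)
        flat[mask] = multipletests(flat[mask], method="holm")[1]
        p.loc[:, :] = flat.reshape(p.shape)
    return ConditionComparisonTable(p_values=p, effect_sizes=d)


def dominance_ranking(table: ConditionComparisonTable) -> tuple[str, ...]:
    """Unimodal conditions by ascending |d| to the multimodal condition.

    The effect size for condition *u* is read from row *u* (its own scale),
    column ``multimodal``.  The first entry is the condition closest to — and
    so contributing most to — the multimodal representation.  Ties break in
    the fixed order visual, auditory, olfactory.
    """
    fixed_order = {"visual": 0, "auditory": 1, "olfactory": 2}
    key = lambda u: (abs(table.effect_sizes.loc[u, "multimodal"]), fixed_order[u])
    return tuple(sorted(UNIMODAL_CONDITIONS, key=key))


def condition_mean_ci(points: np.ndarray) -> tuple[np.ndarray, float]:
    """2-D mean and the radius of an isotropic 95% confidence circle.

    The radius is ``1.96 * sqrt((var_x + var_y) / 2) / sqrt(n)`` — the usual
    normal-theory CI of a mean with the two per-axis variances averaged so
    the region is a circle rather than an ellipse.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    n = len(pts)
    if n < 2:
        raise ValidationError("need at least two points for a confidence circle")
    mean = pts.mean(axis=0)
    var = pts.var(axis=0, ddof=1)
    radius = 1.96 * np.sqrt(var.mean()) / np.sqrt(n)
    return mean, float(radius)


def _barycentric(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    a, b, c = tri
    m = np.column_stack([b - a, c - a])
    det = float(np.linalg.det(m))
    if abs(det) < 1e-12 * max(1.0, float(np.abs(m).max()) ** 2):
        raise DegenerateGeometryError("triangle vertices are (nearly) collinear")
    l2, l3 = np.linalg.solve(m, p - a)
    return np.array([1.0 - l2 - l3, l2, l3])


def point_in_triangle(
    p: Sequence[float], tri: Sequence[Sequence[float]], tol: float = 1e-12
) -> str:
    """Classify a 2-D point against a triangle: ``inside``/``boundary``/``outside``.

    Barycentric coordinates are used; a coordinate within ``tol`` of zero
    counts as the boundary.
    """
    lam = _barycentric(np.asarray(p, float), np.asarray(tri, float))
    if (lam < -tol).any():
        return "outside"
    if (np.abs(lam) <= tol).any():
        return "boundary"
    return "inside"


def _segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    t = np.clip(float(ab @ (p - a)) / float(ab @ ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def circle_triangle_disjoint(
    center: np.ndarray, radius: float, tri: np.ndarray, tol: float = 1e-9
) -> bool:
    """Exact test: is the closed disc disjoint from the closed triangle?"""
    if point_in_triangle(center, tri) != "outside":
        return False
    dist = min(
        _segment_distance(center, tri[i], tri[(i + 1) % 3]) for i in range(3)
    )
    return dist > radius + tol


@dataclass
class TriangleTestResult:
    """Geometry of one 2-D scale projection and the multimodal verdict."""

    projection: tuple[str, str]  # (x scale, y scale)
    means: dict[str, np.ndarray]  # condition -> 2-D mean
    radii: dict[str, float]  # condition -> 95% confidence circle radius
    triangle: np.ndarray  # (3, 2), unimodal means in fixed order V, A, O
    mean_inside: bool
    mean_position: str  # inside | boundary | outside
    circle_triangle_overlap: bool
    overlap_fraction: float
    mc_samples: int
    seed: int


def unimodal_projection_pairs() -> tuple[tuple[str, str], ...]:
    """The three pairs of unimodal scale axes."""
    return tuple(itertools.combinations(UNIMODAL_CONDITIONS, 2))


def all_projection_pairs() -> tuple[tuple[str, str], ...]:
    """All six pairs of the four scale axes."""
    return tuple(itertools.combinations(CONDITIONS, 2))


def triangular_test(
    scales: ScaleMatrix,
    projection_pairs: Sequence[tuple[str, str]] | None = None,
    mc_samples: int = 10_000,
    *,
    seed: int,
) -> list[TriangleTestResult]:
    """Test multimodal containment in the unimodal triangle per 2-D projection.

    For each pair of scale axes the three unimodal condition means form a
    triangle; the multimodal mean and its 95% confidence circle are computed,
    the mean is classified against the triangle, and the circle-triangle
    overlap fraction is estimated by seeded Monte Carlo (points uniform in
    the disc).  The binary overlap verdict comes from an exact
    segment-circle intersection test, cross-checked against the Monte-Carlo
    fraction.
    """
    if projection_pairs is None:
        projection_pairs = unimodal_projection_pairs()
    if mc_samples < 100:
        raise ValidationError("mc_samples must be >= 100")
    for pair in projection_pairs:
        if len(pair) != 2 or pair[0] == pair[1]:
            raise ValidationError(f"projection pair must name two distinct scales: {pair}")
    rng = np.random.default_rng(seed)
    results = []
    for sx, sy in projection_pairs:
        pts = np.column_stack([scales.scale(sx), scales.scale(sy)])
        means, radii = {}, {}
        for cond in CONDITIONS:
            mean, radius = condition_mean_ci(pts[scales.condition_mask(cond)])
            means[cond], radii[cond] = mean, radius
        triangle = np.array([means[c] for c in UNIMODAL_CONDITIONS])
        position = point_in_triangle(means["multimodal"], triangle)
        center, radius = means["multimodal"], radii["multimodal"]
        theta = rng.uniform(0.0, 2.0 * np.pi, mc_samples)
        rr = radius * np.sqrt(rng.uniform(0.0, 1.0, mc_samples))
        samples = center + np.column_stack([rr * np.cos(theta), rr * np.sin(theta)])
        a, b, c = triangle
        m = np.column_stack([b - a, c - a])
        lam23 = np.linalg.solve(m, (samples - a).T).T
        lam = np.column_stack([1.0 - lam23.sum(axis=1), lam23])
        inside = (lam >= -1e-12).all(axis=1)
        overlap_fraction = float(inside.mean())
        disjoint = circle_triangle_disjoint(center, radius, triangle)
        overlap = not disjoint
        if overlap != (overlap_fraction > 0):
            log.warning(
                "projection %s: Monte-Carlo overlap fraction %.4f disagrees with "
                "the exact intersection test (overlap=%s); reporting the exact verdict",
                (sx, sy), overlap_fraction, overlap,
            )
        results.append(TriangleTestResult(
            projection=(sx, sy),
            means=means,
            radii=radii,
            triangle=triangle,
            mean_inside=position != "outside",
            mean_position=position,
            circle_triangle_overlap=overlap,
            overlap_fraction=overlap_fraction,
            mc_samples=mc_samples,
            seed=seed,
        ))
    return results
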