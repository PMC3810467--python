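"""Leave-one-subject-out semantic scales.

A semantic scale quantifies, for every participant, how similar their
aggregated narrative representation is to one target cue condition.  The
target condition is coded +1 and the other three conditions -1; ordinary
least squares predicts this coding from the representation coordinates, and
to avoid leakage each participant's value is predicted by a model fitted on
the other participants only (leave one subject out).  To limit over-fitting,
only the dimensions most correlated with the coding on the training fold are
used — half as many dimensions as there are predicted data points.

Scales are first computed within each grammatical word class and then
combined by a second leave-one-subject-out regression whose features are the
per-class scale values.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .narratives import ALL_WORDS, CONDITIONS, RepresentationSet, WORD_CLASSES

log = logging.getLogger(__name__)

__all__ = [
    "SemanticScale",
    "ScaleMatrix",
    "code_conditions",
    "rank_dimensions",
    "loo_scale",
    "class_scales",
    "combine_scales",
    "evaluate_scale",
    "z_transform",
    "standard_z",
    "build_scale_matrix",
]

MIN_PARTICIPANTS = 4


def code_conditions(conditions: Sequence[str], target: str) -> np.ndarray:
    """+1 for participants in the target condition, -1 for everyone else."""
    if target not in CONDITIONS:
        raise ValidationError(f"unknown target condition {target!r}")
    unknown = sorted(set(conditions) - set(CONDITIONS))
    if unknown:
        raise ValidationError(f"unknown condition labels: {unknown}")
    return np.where(np.asarray(conditions) == target, 1.0, -1.0)


def rank_dimensions(train_x: np.ndarray, train_codes: np.ndarray) -> np.ndarray:
    """Dimension indices by descending |Pearson r| with the condition codes.

    Zero-variance dimensions score 0 and sort last; ties break by ascending
    index (stable sort).
    """
    x = np.asarray(train_x, dtype=float)
    y = np.asarray(train_codes, dtype=float)
    if x.ndim != 2 or len(x) != len(y):
        raise ValidationError("train_x must be 2-D with one row per code")
    if len(y) < 2:
        raise ValidationError("need at least two training points")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ yc / np.where(denom > 0, denom, 1.0), 0.0)
    return np.argsort(-np.abs(r), kind="stable")


def _ols_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> float:
    """Least-squares fit with intercept; minimum-norm solution if singular."""
    a = np.column_stack([np.ones(len(train_x)), train_x])
    coef, _, rank, _ = np.linalg.lstsq(a, train_y, rcond=None)
    if rank < a.shape[1]:
        log.debug("singular fold design (rank %d < %d); minimum-norm solution",
                  rank, a.shape[1])
    return float(coef[0] + test_x @ coef[1:])


def loo_scale(
    representations: np.ndarray,
    codes: np.ndarray,
    subset_size: int | None = None,
) -> np.ndarray:
    """Leave-one-subject-out predictions of the ±1 coding (the semantic scale).

    For each participant the remaining participants form the training fold;
    dimensions are re-ranked on that fold, the top ``subset_size`` (default:
    half the number of predicted data points) enter an OLS fit with
    intercept, and the fitted function is applied to the held-out
    representation.
    """
    x = np.asarray(representations, dtype=float)
    y = np.asarray(codes, dtype=float)
    n, k = x.shape
    if n < MIN_PARTICIPANTS:
        raise ValidationError(f"need at least {MIN_PARTICIPANTS} participants, got {n}")
    if len(y) != n:
        raise ValidationError("codes length does not match representations")
    m = n // 2 if subset_size is None else int(subset_size)
    m = max(1, min(m, k))
    predictions = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        dims = rank_dimensions(x[mask], y[mask])[:m]
        predictions[i] = _ols_predict(x[mask][:, dims], y[mask], x[i, dims])
        mask[i] = True
    return predictions


@dataclass
class SemanticScale:
    """LOO-predicted values of one target-condition coding, per participant."""

    target: str
    scope: str  # "all", a word class, or "combined"
    participant_ids: tuple[str, ...]
    values: np.ndarray
    subset_size: int | None = None

    def z_values(self) -> np.ndarray:
        return z_transform(self.values)


def class_scales(
    representations: Mapping[str, RepresentationSet],
    codes: np.ndarray,
    classes: Sequence[str] = WORD_CLASSES,
) -> dict[str, np.ndarray]:
    """One LOO scale per word class, aligned to the full participant list.

    A participant without a usable representation in some class receives the
    neutral value 0 on that class's scale.  Classes with fewer than four
    usable participants are dropped with a warning.
    """
    out: dict[str, np.ndarray] = {}
    for cls in classes:
        if cls not in representations:
            continue
        rep = representations[cls]
        usable = rep.present
        n_usable = int(usable.sum())
        if n_usable < MIN_PARTICIPANTS:
            log.warning("word class %r dropped: only %d usable participants",
                        cls, n_usable)
            continue
        # A class in which every usable participant has the same representation
        # (e.g. a one-word class) cannot discriminate between participants;
        # its LOO predictions would only echo the left-out-dependent training
        # mean, a leakage artifact, so the class is dropped.
        if rep.matrix[usable].var(axis=0).sum() < 1e-16:
            log.warning("word class %r dropped: identical representations", cls)
            continue
        values = np.zeros(len(rep.participant_ids))
        values[usable] = loo_scale(
            rep.matrix[usable], np.asarray(codes)[usable],
            subset_size=n_usable // 2,
        )
        # A class whose scale is constant across usable participants (e.g. a
        # one-word class where every representation is the same unit vector)
        # carries no information; with zero-filled absences it would also be
        # collinear with the regression intercept on some folds.
        spread = float(np.std(values[usable]))
        if spread < 1e-10 * max(1.0, float(np.abs(values[usable]).max())):
            log.warning("word class %r dropped: constant scale values", cls)
            continue
        if not usable.all():
            log.info("word class %r: %d participants filled with neutral 0",
                     cls, int((~usable).sum()))
        out[cls] = values
    return out


def combine_scales(
    class_scale_values: Mapping[str, np.ndarray], codes: np.ndarray
) -> np.ndarray:
    """Combine per-class scales with a second LOO regression.

    The features are the per-class scale values themselves; no
    dimension-subset step is applied since there are at most 14 features.
    """
    if not class_scale_values:
        raise ValidationError("no class scales to combine")
    features = np.column_stack([class_scale_values[c] for c in class_scale_values])
    y = np.asarray(codes, dtype=float)
    n = len(y)
    if n < MIN_PARTICIPANTS:
        raise ValidationError(f"need at least {MIN_PARTICIPANTS} participants")
    predictions = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        predictions[i] = _ols_predict(features[mask], y[mask], features[i])
        mask[i] = True
    return predictions


def evaluate_scale(values: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """Pearson r between the ±1 codes and the predictions, one-sided p for r > 0.

    A significantly positive correlation means the semantic representation
    predicts the condition.
    """
    values = np.asarray(values, dtype=float)
    codes = np.asarray(codes, dtype=float)
    if len(values) < MIN_PARTICIPANTS:
        raise ValidationError("need at least four data points")
    if np.std(values) == 0:
        raise ValidationError("predictions have zero variance; r undefined")
    res = stats.pearsonr(codes, values, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def standard_z(values: np.ndarray) -> np.ndarray:
    """Conventional z-scores ``(x - mean) / sd`` (sample sd, ddof=1)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("zero standard deviation")
    return (x - x.mean()) / sd


def z_transform(values: np.ndarray) -> np.ndarray:
    """Z-scores additionally divided by ``sqrt(n - 1)``.

    This is the transform used for reporting scale values; ``standard_z`` is
    available for conventional diagnostics.
    """
    x = np.asarray(values, dtype=float)
    return standard_z(x) / np.sqrt(len(x) - 1)


@dataclass
class ScaleMatrix:
    """Participants × four combined semantic scales, plus condition labels."""

    participant_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    values: pd.DataFrame  # index participant_ids, one column per target

    def __post_init__(self) -> None:
        if self.values.empty:
            raise ValidationError("scale matrix has no columns")
        unknown = set(self.values.columns) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown scale targets: {sorted(unknown)}")
        if self.values.isna().any().any():
            raise ValidationError("scale matrix contains missing cells")

    def scale(self, target: str) -> np.ndarray:
        return self.values[target].to_numpy()

    def condition_mask(self, condition: str) -> np.ndarray:
        return np.asarray(self.conditions) == condition

    def to_frame(self) -> pd.DataFrame:
        frame = self.values.copy()
        frame.insert(0, "condition", list(self.conditions))
        frame.index.name = "participant_id"
        return frame


def build_scale_matrix(
    representations: Mapping[str, RepresentationSet],
    per_class: bool = True,
    targets: Sequence[str] = CONDITIONS,
) -> ScaleMatrix:
    """Compute the four combined semantic scales from participant representations.

    With ``per_class=True`` the per-word-class scales are computed and
    combined (the full procedure); with ``per_class=False`` a single LOO
    scale on the all-words representations is used, which is statistically
    equivalent when the word classes carry no differential information and is
    much cheaper in simulation studies.
    """
    if ALL_WORDS not in representations:
        raise ValidationError("all-words representations are required")
    base = representations[ALL_WORDS]
    if not base.present.all():
        absent = [p for p, ok in zip(base.participant_ids, base.present) if not ok]
        raise ValidationError(
            f"participants without an all-words representation: {absent}"
        )
    columns: dict[str, np.ndarray] = {}
    for target in targets:
        codes = code_conditions(base.conditions, target)
        if per_class:
            per_cls = class_scales(representations, codes)
            if per_cls:
                columns[target] = combine_scales(per_cls, codes)
            else:
                log.warning("no usable word-class scale; falling back to all-words")
                columns[target] = loo_scale(base.matrix, codes)
        else:
            columns[target] = loo_scale(base.matrix, codes)
    values = pd.DataFrame(columns, index=list(base.participant_ids))
    return ScaleMatrix(
        participant_ids=base.participant_ids,
        conditions=base.conditions,
        values=values,
    )
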