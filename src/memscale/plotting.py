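"""Diagnostic plots: pairwise scale scatters and condition means with circles."""

from __future__ import annotations

import numpy as np

from .hypotheses import TriangleTestResult, all_projection_pairs
from .narratives import CONDITIONS, UNIMODAL_CONDITIONS
from .scales import ScaleMatrix

CONDITION_COLORS = {
    "visual": "tab:red",
    "auditory": "tab:blue",
    "olfactory": "tab:green",
    "multimodal": "gold",
}


def plot_scale_pairs(scales: ScaleMatrix, pairs=None):
    """Scatter of participants on every pairwise combination of the scales."""
    import matplotlib.pyplot as plt

    pairs = pairs or all_projection_pairs()
    ncols = 3
    nrows = int(np.ceil(len(pairs) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 4 * nrows),
                             squeeze=False)
    for ax, (sx, sy) in zip(axes.flat, pairs):
        for cond in CONDITIONS:
            mask = scales.condition_mask(cond)
            ax.scatter(scales.scale(sx)[mask], scales.scale(sy)[mask],
                       marker="x", color=CONDITION_COLORS[cond], label=cond)
            ax.scatter(*np.column_stack([scales.scale(sx)[mask],
                                         scales.scale(sy)[mask]]).mean(axis=0),
                       marker="o", facecolors="none",
                       edgecolors=CONDITION_COLORS[cond], s=120)
        ax.set_xlabel(f"{sx} scale")
        ax.set_ylabel(f"{sy} scale")
    for ax in axes.flat[len(pairs):]:
        ax.axis("off")
    axes.flat[0].legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_triangle(result: TriangleTestResult):
    """Condition means, 95% confidence circles and the unimodal triangle."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    tri = np.vstack([result.triangle, result.triangle[:1]])
    ax.plot(tri[:, 0], tri[:, 1], color="gray", lw=1)
    for cond in CONDITIONS:
        mean, radius = result.means[cond], result.radii[cond]
        ax.scatter(*mean, marker="x", color=CONDITION_COLORS[cond], label=cond)
        ax.add_patch(plt.Circle(mean, radius, fill=False,
                                color=CONDITION_COLORS[cond]))
    sx, sy = result.projection
    ax.set_xlabel(f"{sx} scale")
    ax.set_ylabel(f"{sy} scale")
    ax.set_aspect("equal")
    ax.legend(fontsize=8)
    verdict = "inside" if result.mean_inside else "outside"
    ax.set_title(f"multimodal mean {verdict}; overlap {result.overlap_fraction:.2f}")
    fig.tight_layout()
    return fig
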