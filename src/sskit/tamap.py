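"""Triangular Affinity Map: 2-D placement of a target population relative
to three anchor populations from gene-set-score similarities.

All six similarity inputs (three target-anchor and three anchor-anchor)
are jointly min-max normalized.  The three internal angles at the target
vertex are proportional to the anchor-pair dissimilarities and sum to 360
degrees; the edge from the target to each anchor has length
``epsilon + (1 - normalized target-anchor similarity)``, so similar pairs
sit closer.  The target is placed at the origin with the first anchor on
the positive y-axis and anchors ordered counterclockwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, ValidationError
from .markers import score_gene_set

__all__ = ["TAMapLayout", "mean_group_scores", "tamap_layout", "plot_tamap"]


@dataclass
class TAMapLayout:
    """Normalized similarities, target-vertex angles, edge lengths, coords."""

    normalized_similarities: dict  # six values in [0, 1]
    angles: np.ndarray  # degrees, at the target vertex, sum 360
    edge_lengths: np.ndarray  # target->anchor, >= epsilon
    coords: pd.DataFrame  # point, x, y

    def __post_init__(self) -> None:
        if abs(self.angles.sum() - 360.0) > 1e-9:
            raise ValidationError("angles must sum to 360 degrees")
        if np.any(self.edge_lengths <= 0):
            raise ValidationError("edge lengths must be positive")


def mean_group_scores(
    dataset: ExpressionDataset,
    gene_sets: dict,
    group_labels,
    n_bins: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Groups x gene-sets matrix of mean per-cell gene-set scores."""
    group_labels = np.asarray(group_labels)
    if len(group_labels) != dataset.n_cells:
        raise ValidationError("group labels must align with cells")
    groups = pd.unique(group_labels)
    for g in groups:
        if (group_labels == g).sum() == 0:
            raise ValidationError(f"empty group {g!r}")
    rng = np.random.default_rng(seed)
    out = {}
    for name, genes in gene_sets.items():
        cell_scores = score_gene_set(
            dataset, genes, n_bins=n_bins, seed=int(rng.integers(0, 2**31))
        )
        out[name] = [float(cell_scores[group_labels == g].mean()) for g in groups]
    return pd.DataFrame(out, index=pd.Index(groups, name="group"))


def tamap_layout(
    target_anchor_sims: Sequence[float],
    anchor_pair_sims: Sequence[float],
    epsilon: float = 0.05,
    anchor_names: Sequence[str] = ("A", "B", "C"),
    target_name: str = "target",
) -> TAMapLayout:
    """Compute the triangular layout from six similarity values.

    ``target_anchor_sims`` are the target's similarities to anchors A, B, C;
    ``anchor_pair_sims`` are the pair similarities (A,B), (B,C), (C,A).
    If all pair dissimilarities vanish the angles default to 120 degrees
    each; if all six inputs are equal the joint min-max normalization maps
    them to the midpoint 0.5.
    """
    ta = np.asarray(target_anchor_sims, dtype=np.float64)
    pp = np.asarray(anchor_pair_sims, dtype=np.float64)
    if ta.shape != (3,) or pp.shape != (3,):
        raise ValidationError("three target-anchor and three pair similarities required")
    allv = np.concatenate([ta, pp])
    if not np.all(np.isfinite(allv)):
        raise ValidationError("non-finite similarity input")
    lo, hi = allv.min(), allv.max()
    if hi > lo:
        norm = (allv - lo) / (hi - lo)
    else:
        norm = np.full(6, 0.5)
    ta_n, pp_n = norm[:3], norm[3:]

    w = 1.0 - pp_n
    if w.sum() == 0:
        angles = np.full(3, 120.0)
    else:
        angles = 360.0 * w / w.sum()
    # exact closure despite float division
    angles[2] = 360.0 - angles[0] - angles[1]

    lengths = epsilon + (1.0 - ta_n)

    # target at origin; anchor A on the +y axis; B, C counterclockwise
    headings = np.deg2rad(90.0 + np.concatenate([[0.0], np.cumsum(angles[:2])]))
    xy = np.stack([lengths * np.cos(headings), lengths * np.sin(headings)], axis=1)
    coords = pd.DataFrame(
        {
            "point": [target_name, *anchor_names],
            "x": [0.0, *xy[:, 0]],
            "y": [0.0, *xy[:, 1]],
        }
    )
    sims = {
        **{f"target~{n}": float(v) for n, v in zip(anchor_names, ta_n)},
        **{
            f"{a}~{b}": float(v)
            for (a, b), v in zip(
                [(anchor_names[0], anchor_names[1]),
                 (anchor_names[1], anchor_names[2]),
                 (anchor_names[2], anchor_names[0])],
                pp_n,
            )
        },
    }
    return TAMapLayout(
        normalized_similarities=sims,
        angles=angles,
        edge_lengths=lengths,
        coords=coords,
    )


def plot_tamap(layout: TAMapLayout, ax=None):
    """Minimal rendering: edges from the target to each anchor, labelled."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    coords = layout.coords.set_index("point")
    target = coords.iloc[0]
    for name, row in coords.iloc[1:].iterrows():
        ax.plot([target.x, row.x], [target.y, row.y], "-", color="0.4")
        ax.annotate(str(name), (row.x, row.y))
    ax.scatter(coords.x, coords.y, zorder=3)
    ax.annotate(str(coords.index[0]), (target.x, target.y))
    ax.set_aspect("equal")
    return ax
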