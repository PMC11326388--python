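"""Laminar assignment and compositional statistics for spatial data.

Interneurons inherit a cortical layer from the identities of their five
nearest excitatory neighbours (KD-tree, leaf size 6), with plurality voting
and nearest-tied-class tie breaking.  Composition tables summarize subtype
fractions per group; group comparisons use the two-sided Wilcoxon rank-sum
test, exact for small samples (combined n <= 25 without ties) and
normal-approximated with tie correction otherwise, without correction for
multiple comparisons.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.neighbors import KDTree

from .dataset import ValidationError

__all__ = ["assign_layers", "composition_table", "rank_sum_compare"]

_EXACT_MAX_N = 25


def assign_layers(
    interneuron_coords: np.ndarray,
    excitatory_coords: np.ndarray,
    excitatory_layers: Sequence,
    k: int = 5,
    leaf_size: int = 6,
) -> pd.DataFrame:
    """Assign each interneuron the plurality layer of its ``k`` nearest
    excitatory neighbours.

    Ties between equally frequent layers are broken by the layer of the
    nearest neighbour belonging to a tied class.  Returns one row per
    interneuron with the assignment, the neighbour layers and distances
    (nearest first), and the vote margin (plurality count minus runner-up).
    """
    xi = np.atleast_2d(np.asarray(interneuron_coords, dtype=np.float64))
    xe = np.atleast_2d(np.asarray(excitatory_coords, dtype=np.float64))
    layers = np.asarray(excitatory_layers)
    if len(layers) != xe.shape[0]:
        raise ValidationError("excitatory_layers must align with excitatory_coords")
    if k > xe.shape[0]:
        raise ValidationError(f"k={k} exceeds the {xe.shape[0]} excitatory cells")
    tree = KDTree(xe, leaf_size=leaf_size)
    dist, idx = tree.query(xi, k=k)
    records = []
    for i in range(xi.shape[0]):
        nb_layers = layers[idx[i]]
        values, counts = np.unique(nb_layers, return_counts=True)
        top = counts.max()
        tied = set(values[counts == top])
        if len(tied) == 1:
            assigned = values[counts == top][0]
        else:  # label of the nearest neighbour in a tied class
            assigned = next(l for l in nb_layers if l in tied)
        runner_up = max((c for v, c in zip(values, counts) if v != assigned), default=0)
        records.append(
            {
                "assigned_layer": assigned,
                "neighbor_layers": list(nb_layers),
                "neighbor_distances": list(dist[i]),
                "vote_margin": int(top - runner_up),
            }
        )
    return pd.DataFrame.from_records(records)


def composition_table(
    cell_table: pd.DataFrame,
    type_col: str,
    group_cols,
    denominator: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-group cell-type fractions (groups in rows, types in columns).

    With the default denominator (the group's total cell count) each row
    sums to 1.  An external per-group ``denominator`` series (for example a
    reference population size or a tissue-length normalizer) can replace the
    group total, in which case rows are rates rather than fractions.
    """
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    for col in [type_col, *group_cols]:
        if col not in cell_table.columns:
            raise ValidationError(f"missing column {col!r}")
    counts = (
        cell_table.groupby(group_cols + [type_col], observed=True)
        .size()
        .unstack(type_col, fill_value=0)
    )
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"dropping empty groups: {list(counts.index[empty])}", stacklevel=2)
        counts = counts[~empty]
    if denominator is None:
        denom = counts.sum(axis=1)
    else:
        denom = denominator.reindex(counts.index)
        if denom.isna().any():
            raise ValidationError("denominator missing for some groups")
    return counts.div(denom, axis=0)


def rank_sum_compare(
    values: pd.DataFrame,
    groups,
    group_a,
    group_b,
    two_sided: bool = True,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of two groups, column by column.

    ``values`` holds one row per replicate (for example per ROI) and one
    column per cell type; ``groups`` assigns each row to a group.  The exact
    null distribution is used for combined n <= 25 when there are no ties;
    otherwise the normal approximation with tie correction.  No
    multiple-testing correction is applied.
    """
    groups = np.asarray(groups)
    a_mask, b_mask = groups == group_a, groups == group_b
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValidationError("each group needs at least 2 replicates")
    alternative = "two-sided" if two_sided else "greater"
    records = []
    for col in values.columns:
        a = values.loc[a_mask, col].to_numpy(dtype=np.float64)
        b = values.loc[b_mask, col].to_numpy(dtype=np.float64)
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            records.append({"type": col, "statistic": len(a) * len(b) / 2.0, "p": 1.0})
            continue
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(pooled) <= _EXACT_MAX_N and not has_ties) else "asymptotic"
        stat, p = mannwhitneyu(a, b, alternative=alternative, method=method)
        records.append({"type": col, "statistic": float(stat), "p": float(p)})
    return pd.DataFrame.from_records(records)
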