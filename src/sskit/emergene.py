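"""Cluster-free differential transcriptomic analysis across conditions.

The method scores genes, then cells, without relying on cluster boundaries:

1. *Within-condition pattern score*: each gene's expression is diffused
   (a) over the k-nearest-neighbour graph and (b) over k random cells; the
   cosine similarity of each diffusion to the original expression vector is
   compared.  Genes with locally coherent expression deviate little under
   kNN diffusion but strongly under random diffusion, so the difference of
   cosines is large.
2. *Cross-condition differential score*: for every cell, the gene is
   diffused over its k nearest same-condition neighbours and its k nearest
   other-condition neighbours in a shared embedding; ``1 - cos`` of the two
   diffused vectors is large for genes whose local pattern depends on
   condition.
3. The top genes of both scores form a combinatorial signature.  Each cell
   receives the mean normalized expression of the signature, normalized
   against Monte Carlo control gene sets matched on set size, expression
   mean and expression variance; empirical one-sided p-values are computed
   from the pooled control distribution across all cells and control sets.
4. Cluster-level records summarize per-cell p-values with a gliding
   percentile threshold (50th by default); clusters with fewer than 10
   cells are reported but marked not analyzed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import ExpressionDataset, NeighborGraph, RunConfig, ValidationError
from .markers import GeneSignature

__all__ = [
    "EmergeneResult",
    "diffuse_local",
    "diffuse_random",
    "gene_pattern_score",
    "cross_condition_score",
    "build_signature",
    "score_cells_permutation",
    "cluster_significance",
    "run_emergene",
]

_SD_FLOOR = 1e-8
_MIN_CLUSTER_SIZE = 10


@dataclass
class EmergeneResult:
    """Per-cell scores and p-values plus cluster-level significance records."""

    signature: GeneSignature
    raw_score: np.ndarray
    norm_score: np.ndarray
    p_cell: np.ndarray
    cluster_records: Optional[pd.DataFrame] = None
    gene_scores: Optional[pd.DataFrame] = None


def _as_csr(x) -> sp.csr_matrix:
    return x.tocsr() if sp.issparse(x) else sp.csr_matrix(np.asarray(x, dtype=np.float64))


def _mean_adjacency(indices: np.ndarray, n_cols: int) -> sp.csr_matrix:
    """Row-stochastic adjacency averaging over the listed neighbour columns."""
    n, k = indices.shape
    data = np.full(n * k, 1.0 / k)
    indptr = np.arange(0, n * k + 1, k)
    return sp.csr_matrix((data, indices.ravel(), indptr), shape=(n, n_cols))


def diffuse_local(normed_expr, graph: NeighborGraph) -> sp.csr_matrix:
    """Mean expression over each cell's k nearest neighbours (self excluded)."""
    x = _as_csr(normed_expr)
    if graph.n_cells != x.shape[0]:
        raise ValidationError(
            f"graph covers {graph.n_cells} cells but expression has {x.shape[0]}"
        )
    return (_mean_adjacency(graph.indices, x.shape[0]) @ x).tocsr()


def diffuse_random(normed_expr, k: int, seed: int = 0) -> sp.csr_matrix:
    """Mean expression over k uniformly sampled cells per cell (self excluded)."""
    x = _as_csr(normed_expr)
    n = x.shape[0]
    if k <= 0:
        raise ValidationError("k must be positive")
    if k >= n:
        raise ValidationError(f"k={k} must be below n_cells={n}")
    rng = np.random.default_rng(seed)
    indices = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        draw = rng.choice(n - 1, size=k, replace=False)
        draw[draw >= i] += 1  # skip self
        indices[i] = draw
    return (_mean_adjacency(indices, n) @ x).tocsr()


def _columnwise_cos(a: sp.csr_matrix, b: sp.csr_matrix) -> np.ndarray:
    """cos between matching columns; 0 where either column is all-zero."""
    dot = np.asarray(a.multiply(b).sum(axis=0)).ravel()
    na = np.sqrt(np.asarray(a.multiply(a).sum(axis=0)).ravel())
    nb = np.sqrt(np.asarray(b.multiply(b).sum(axis=0)).ravel())
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, dot / np.maximum(denom, 1e-300), 0.0)
    return cos


def gene_pattern_score(
    dataset: ExpressionDataset,
    graph: NeighborGraph,
    k: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-gene within-condition pattern score.

    ``s_g = cos(x_g, local diffusion) - cos(x_g, random diffusion)``; genes
    with all-zero expression score 0 (both cosines are defined as 0).
    """
    x = dataset.require_normalized()
    k = k or graph.k
    local = diffuse_local(x, graph)
    rand = diffuse_random(x, k=k, seed=seed)
    return _columnwise_cos(x, local) - _columnwise_cos(x, rand)


def _knn_rows(
    query: np.ndarray, ref: np.ndarray, k: int, self_map: Optional[np.ndarray] = None
) -> np.ndarray:
    """Brute-force k nearest rows of ``ref`` for each row of ``query``.

    Ties broken by reference row index ascending.  ``self_map[i]`` gives the
    reference row to exclude for query row i (for same-set queries).
    """
    nq, nr = query.shape[0], ref.shape[0]
    need = k + (1 if self_map is not None else 0)
    if need > nr:
        raise ValidationError(f"need {need} reference cells, have {nr}")
    out = np.empty((nq, k), dtype=np.int64)
    sq_r = (ref**2).sum(axis=1)
    idx_all = np.arange(nr)
    chunk = max(1, int(2**22 // max(nr, 1)))
    for start in range(0, nq, chunk):
        stop = min(start + chunk, nq)
        d2 = ((query[start:stop] ** 2).sum(axis=1)[:, None]
              - 2 * (query[start:stop] @ ref.T) + sq_r[None, :])
        for r, i in enumerate(range(start, stop)):
            order = np.lexsort((idx_all, d2[r]))
            if self_map is not None:
                order = order[order != self_map[i]]
            out[i] = order[:k]
    return out


def cross_condition_score(
    dataset: ExpressionDataset,
    embedding: np.ndarray,
    condition_col: str = "condition",
    k: int = 30,
    conditions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Per-gene cross-condition deviation score.

    For each cell, the gene is diffused over the k nearest same-condition
    cells and the k nearest other-condition cells in the shared embedding;
    ``d_g = 1 - cos(u_g, v_g)`` between the two diffused vectors.  Genes
    with an all-zero diffused vector score 0.  ``conditions`` overrides the
    cell-table column (used by the pipeline to score a permuted-label
    baseline: the raw deviation depends on a gene's expression level, so
    differential genes are ranked by the deviation in excess of the
    label-permuted value, mirroring the random-diffusion baseline of the
    within-condition score).
    """
    x = dataset.require_normalized()
    emb = np.asarray(embedding, dtype=np.float64)
    if emb.shape[0] != dataset.n_cells:
        raise ValidationError("embedding must cover all cells")
    cond = (
        np.asarray(conditions)
        if conditions is not None
        else dataset.cell_table[condition_col].to_numpy()
    )
    if len(cond) != dataset.n_cells:
        raise ValidationError("condition labels must cover all cells")
    levels = np.unique(cond)
    if len(levels) != 2:
        raise ValidationError(f"exactly 2 conditions required, got {list(levels)}")
    n = dataset.n_cells
    within_idx = np.empty((n, k), dtype=np.int64)
    cross_idx = np.empty((n, k), dtype=np.int64)
    for level in levels:
        same = np.flatnonzero(cond == level)
        other = np.flatnonzero(cond != level)
        if len(same) < k + 1:
            raise ValidationError(
                f"condition {level!r} has {len(same)} cells; needs at least {k + 1}"
            )
        w = _knn_rows(emb[same], emb[same], k, self_map=np.arange(len(same)))
        c = _knn_rows(emb[same], emb[other], k)
        within_idx[same] = same[w]
        cross_idx[same] = other[c]
    u = _mean_adjacency(within_idx, n) @ x
    v = _mean_adjacency(cross_idx, n) @ x
    cos = _columnwise_cos(u.tocsr(), v.tocsr())
    zero = np.asarray(abs(u).sum(axis=0)).ravel() * np.asarray(abs(v).sum(axis=0)).ravel() == 0
    d = 1.0 - cos
    d[zero] = 0.0
    return d


def _top_by_score(scores: np.ndarray, gene_ids: np.ndarray, n: int) -> list:
    order = np.lexsort((gene_ids, -scores))
    return [gene_ids[i] for i in order[: min(n, len(gene_ids))]]


def build_signature(
    within_scores: np.ndarray,
    cross_scores: np.ndarray,
    gene_ids: Sequence[str],
    n_top_within: int = 50,
    n_top_cross: int = 50,
    name: str = "emergene",
) -> GeneSignature:
    """Union of the top genes by each score, with per-gene provenance.

    Genes appearing in both tops get provenance ``"both"``; the signature is
    ordered by each gene's best rank across the two score lists, ties by
    gene id ascending.
    """
    gene_ids = np.asarray(gene_ids).astype(str)
    within = np.asarray(within_scores, dtype=np.float64)
    cross = np.asarray(cross_scores, dtype=np.float64)
    if not (len(gene_ids) == len(within) == len(cross)):
        raise ValidationError("score vectors must align with gene ids")
    top_w = _top_by_score(within, gene_ids, n_top_within)
    top_c = _top_by_score(cross, gene_ids, n_top_cross)
    union = set(top_w) | set(top_c)
    if not union:
        raise ValidationError("empty signature union")
    rank_w = {g: r for r, g in enumerate(top_w)}
    rank_c = {g: r for r, g in enumerate(top_c)}
    big = len(gene_ids) + 1
    ordered = sorted(union, key=lambda g: (min(rank_w.get(g, big), rank_c.get(g, big)), g))
    lookup = {g: i for i, g in enumerate(gene_ids)}
    provenance = [
        "both" if (g in rank_w and g in rank_c)
        else ("specific" if g in rank_w else "differential")
        for g in ordered
    ]
    return GeneSignature(
        name=name,
        genes=ordered,
        within_scores=[float(within[lookup[g]]) for g in ordered],
        cross_scores=[float(cross[lookup[g]]) for g in ordered],
        provenance=provenance,
    )


def _joint_bins(
    mean: np.ndarray, var: np.ndarray, n_bins_mean: int, n_bins_var: int
) -> np.ndarray:
    """Joint mean x variance bins: mean deciles, variance deciles within."""
    n = len(mean)
    order = np.argsort(mean, kind="stable")
    mean_bin = np.empty(n, dtype=np.int64)
    mean_bin[order] = np.arange(n) * n_bins_mean // n
    joint = np.empty(n, dtype=np.int64)
    for b in range(n_bins_mean):
        members = np.flatnonzero(mean_bin == b)
        sub = members[np.argsort(var[members], kind="stable")]
        vb = np.arange(len(sub)) * n_bins_var // max(len(sub), 1)
        joint[sub] = b * n_bins_var + vb
    return joint


def score_cells_permutation(
    dataset: ExpressionDataset,
    signature: GeneSignature,
    n_control_sets: int = 10000,
    n_bins_mean: int = 10,
    n_bins_var: int = 10,
    seed: int = 0,
) -> EmergeneResult:
    """Per-cell signature scores with matched-control empirical p-values.

    Each control set replaces every signature gene with a uniform draw from
    its joint mean/variance bin.  Raw score = mean normalized expression
    over the set; per cell, ``z = (raw - mean_ctrl) / sd_ctrl`` (sd floored
    at 1e-8); the one-sided empirical p-value pools the normalized control
    scores across all cells and control sets:

        p_i = (1 + #{control z >= z_i}) / (1 + n_cells * n_control_sets)
    """
    if len(signature) == 0:
        raise ValidationError("signature is empty")
    x = dataset.require_normalized()
    n_cells = x.shape[0]
    sig_idx = dataset.gene_indices(signature.genes)
    gmean = np.asarray(x.mean(axis=0)).ravel()
    gsq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    gvar = np.maximum(gsq - gmean**2, 0.0)
    bins = _joint_bins(gmean, gvar, n_bins_mean, n_bins_var)

    rng = np.random.default_rng(seed)
    n_sig = len(sig_idx)
    draws = np.empty((n_control_sets, n_sig), dtype=np.int64)
    warned = False
    for j, g in enumerate(sig_idx):
        pool = np.flatnonzero(bins == bins[g])
        if len(pool) == 1 and not warned:
            warnings.warn(
                "control bin with a single gene; control draws are degenerate "
                "(sampling with replacement)",
                stacklevel=2,
            )
            warned = True
        draws[:, j] = pool[rng.integers(0, len(pool), size=n_control_sets)]

    raw = np.asarray(x[:, sig_idx].mean(axis=1)).ravel()
    # control raw scores as X @ W, W[g, s] = multiplicity of g in set s / n_sig
    w = sp.coo_matrix(
        (
            np.full(draws.size, 1.0 / n_sig),
            (draws.ravel(), np.repeat(np.arange(n_control_sets), n_sig)),
        ),
        shape=(x.shape[1], n_control_sets),
    ).tocsr()
    ctrl = np.asarray((x @ w).todense())  # n_cells x n_control_sets
    ctrl_mean = ctrl.mean(axis=1)
    ctrl_sd = np.maximum(ctrl.std(axis=1), _SD_FLOOR)
    z = (raw - ctrl_mean) / ctrl_sd
    z_ctrl = (ctrl - ctrl_mean[:, None]) / ctrl_sd[:, None]
    pooled = np.sort(z_ctrl, axis=None)
    n_pool = pooled.size
    ge = n_pool - np.searchsorted(pooled, z, side="left")
    p = (1.0 + ge) / (1.0 + n_pool)
    return EmergeneResult(signature=signature, raw_score=raw, norm_score=z, p_cell=p)


def cluster_significance(
    p_cell: np.ndarray,
    clusters: Sequence,
    percentile: float = 50.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Cluster-level significance records from per-cell p-values.

    Per cluster: the fraction of cells with ``p < alpha``, the gliding
    p-value (the given percentile of the cluster's p-values, linear
    interpolation), a flag for clusters with at least half their cells
    significant, and an ``analyzed`` marker that is False for clusters of
    fewer than 10 cells.
    """
    p_cell = np.asarray(p_cell, dtype=np.float64)
    clusters = np.asarray(clusters)
    if len(p_cell) != len(clusters):
        raise ValidationError("p-values and cluster labels must align")
    records = []
    for c in pd.unique(clusters):
        mask = clusters == c
        p = p_cell[mask]
        frac = float((p < alpha).mean())
        records.append(
            {
                "cluster": c,
                "n_cells": int(mask.sum()),
                "frac_significant": frac,
                "gliding_p": float(np.percentile(p, percentile)),
                "flagged": bool(frac >= 0.5),
                "analyzed": bool(mask.sum() >= _MIN_CLUSTER_SIZE),
            }
        )
    return pd.DataFrame.from_records(records)


def run_emergene(
    dataset: ExpressionDataset,
    embedding: np.ndarray,
    graph: NeighborGraph,
    clusters: Optional[Sequence] = None,
    condition_col: str = "condition",
    config: Optional[RunConfig] = None,
) -> EmergeneResult:
    """Full cluster-free differential pipeline on a preprocessed dataset.

    Computes within- and cross-condition gene scores, builds the
    combinatorial signature, scores cells against matched controls, and —
    when cluster labels are given — summarizes significance per
    (cluster, condition) group, since a cell population's response is
    condition-specific.
    """
    cfg = config or RunConfig()
    within = gene_pattern_score(
        dataset, graph, k=cfg.emergene_k, seed=cfg.child_seed("emergene-random-diffusion")
    )
    cross_real = cross_condition_score(
        dataset, embedding, condition_col=condition_col, k=cfg.emergene_k
    )
    rng = np.random.default_rng(cfg.child_seed("emergene-null-split"))
    permuted = rng.permutation(dataset.cell_table[condition_col].to_numpy())
    cross_null = cross_condition_score(
        dataset, embedding, k=cfg.emergene_k, conditions=permuted
    )
    cross = cross_real - cross_null
    signature = build_signature(
        within, cross, dataset.gene_ids,
        n_top_within=cfg.n_top_within, n_top_cross=cfg.n_top_cross,
    )
    result = score_cells_permutation(
        dataset,
        signature,
        n_control_sets=cfg.n_control_sets,
        n_bins_mean=cfg.n_bins_mean,
        n_bins_var=cfg.n_bins_var,
        seed=cfg.child_seed("emergene-controls"),
    )
    result.gene_scores = pd.DataFrame(
        {"gene_id": dataset.gene_ids, "within_score": within, "cross_score": cross}
    )
    if clusters is not None:
        cond = dataset.cell_table[condition_col].astype(str).to_numpy()
        group = np.char.add(
            np.char.add(np.asarray(clusters).astype(str), "|"), cond
        )
        result.cluster_records = cluster_significance(
            result.p_cell, group, percentile=cfg.percentile, alpha=cfg.alpha
        )
    return result
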