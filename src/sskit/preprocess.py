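"""Standard single-nucleus processing stages.

Quality control on per-cell metrics, total-count normalization with log1p,
highly-variable-gene selection by analytic Pearson residuals, truncated-SVD
embedding of scaled residuals, an exact k-nearest-neighbour graph, Leiden
community detection, and local re-clustering of selected clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import ExpressionDataset, NeighborGraph, ValidationError

__all__ = [
    "QCThresholds",
    "qc_filter",
    "normalize_log",
    "pearson_residuals",
    "select_hvgs_pearson",
    "embed_svd",
    "knn_graph",
    "cluster_leiden",
    "leiden_local",
]


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs.

    Cells are retained when total counts fall below ``max_counts``, the
    number of detected genes lies strictly between ``min_genes`` and
    ``max_genes``, mitochondrial and ribosomal count fractions fall below
    ``max_mito``/``max_ribo``, and (when a ``doublet_score`` column exists)
    the doublet score falls below ``max_doublet``.
    """

    max_counts: float = 15000
    min_genes: int = 200
    max_genes: int = 4000
    max_mito: float = 0.05
    max_ribo: float = 0.05
    max_doublet: float = 0.25
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_genes >= self.max_genes:
            raise ValidationError("min_genes must be below max_genes")
        for frac in (self.max_mito, self.max_ribo, self.max_doublet):
            if not (0 < frac <= 1):
                raise ValidationError("fraction thresholds must lie in (0, 1]")


def qc_metrics(dataset: ExpressionDataset) -> pd.DataFrame:
    """Per-cell QC metrics: n_counts, n_genes, mito/ribo count fractions."""
    counts = dataset.counts
    n_counts = np.asarray(counts.sum(axis=1)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=1)).ravel()
    mito = np.asarray(counts[:, dataset.gene_table["mito"].to_numpy()].sum(axis=1)).ravel()
    ribo = np.asarray(counts[:, dataset.gene_table["ribo"].to_numpy()].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_mito = np.where(n_counts > 0, mito / np.maximum(n_counts, 1), 0.0)
        frac_ribo = np.where(n_counts > 0, ribo / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame(
        {
            "n_counts": n_counts,
            "n_genes": n_genes,
            "frac_mito": frac_mito,
            "frac_ribo": frac_ribo,
        }
    )


def qc_filter(
    dataset: ExpressionDataset, thresholds: Optional[QCThresholds] = None
):
    """Apply conjunctive cell filters, then drop genes expressed in fewer
    than ``min_cells_per_gene`` retained cells.

    Returns ``(filtered_dataset, report)`` where the report records the
    number of cells failing each criterion (cells may fail several) and the
    retained dimensions.
    """
    th = thresholds or QCThresholds()
    m = qc_metrics(dataset)
    fails = {
        "max_counts": m["n_counts"].to_numpy() >= th.max_counts,
        "min_genes": m["n_genes"].to_numpy() <= th.min_genes,
        "max_genes": m["n_genes"].to_numpy() >= th.max_genes,
        "max_mito": m["frac_mito"].to_numpy() >= th.max_mito,
        "max_ribo": m["frac_ribo"].to_numpy() >= th.max_ribo,
    }
    if "doublet_score" in dataset.cell_table.columns:
        fails["max_doublet"] = (
            dataset.cell_table["doublet_score"].to_numpy() >= th.max_doublet
        )
    keep_cells = ~np.logical_or.reduce(list(fails.values()))
    report = {
        "n_cells_in": dataset.n_cells,
        "n_genes_in": dataset.n_genes,
        "removed_by": {k: int(v.sum()) for k, v in fails.items()},
        "n_cells_retained": int(keep_cells.sum()),
    }
    if not keep_cells.any():
        raise ValidationError(f"no cells pass QC; report: {report}")
    filtered = dataset.subset_cells(keep_cells)
    cells_per_gene = np.asarray((filtered.counts > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= th.min_cells_per_gene
    report["n_genes_removed"] = int((~keep_genes).sum())
    report["n_genes_retained"] = int(keep_genes.sum())
    if not keep_genes.any():
        raise ValidationError(f"no genes pass QC; report: {report}")
    return filtered.subset_genes(keep_genes), report


def normalize_log(
    dataset: ExpressionDataset, target_sum: float = 10000.0
) -> ExpressionDataset:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    The raw counts are left untouched; the result is stored in the
    ``normalized`` layer (sparse, since log1p preserves zeros).
    """
    totals = np.asarray(dataset.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValidationError("zero-count cell present; run QC first")
    scale = target_sum / totals
    normalized = sp.csr_matrix(dataset.counts, dtype=np.float64)
    normalized = sp.diags(scale) @ normalized
    normalized.data = np.log1p(normalized.data)
    out = dataset.copy()
    out.normalized = normalized.tocsr()
    return out


def pearson_residuals(
    counts: sp.spmatrix, theta: float = 100.0, clip: Optional[float] = None
) -> np.ndarray:
    """Analytic Pearson residuals under the null mu_cg = t_c * t_g / T.

    Residuals are ``(x - mu) / sqrt(mu + mu**2/theta)``, optionally clipped
    symmetrically at ``clip`` (conventionally sqrt(n_cells)).
    """
    counts = sp.csr_matrix(counts, dtype=np.float64)
    t_c = np.asarray(counts.sum(axis=1)).ravel()
    t_g = np.asarray(counts.sum(axis=0)).ravel()
    total = t_c.sum()
    if np.any(t_g == 0):
        raise ValidationError("all-zero gene present; run QC first")
    if np.any(t_c == 0):
        raise ValidationError("zero-count cell present; run QC first")
    mu = np.outer(t_c, t_g) / total
    resid = (counts.toarray() - mu) / np.sqrt(mu + mu**2 / theta)
    if clip is not None:
        np.clip(resid, -clip, clip, out=resid)
    return resid


def select_hvgs_pearson(
    dataset: ExpressionDataset, n_top: int = 5000, theta: float = 100.0
) -> list:
    """Rank genes by Pearson-residual variance; return the top ``n_top`` ids.

    Residuals are clipped at sqrt(n_cells) before the variance ranking, the
    standard stabilization against rare extreme cells.  Ties are broken by
    gene id ascending.
    """
    resid = pearson_residuals(
        dataset.counts, theta=theta, clip=float(np.sqrt(dataset.n_cells))
    )
    var = resid.var(axis=0)
    gene_ids = dataset.gene_ids.astype(str)
    order = np.lexsort((gene_ids, -var))
    n = min(n_top, dataset.n_genes)
    return [str(g) for g in gene_ids[order[:n]]]


def embed_svd(
    dataset: ExpressionDataset,
    hvgs: Sequence[str],
    n_comps: int = 50,
    theta: float = 100.0,
) -> np.ndarray:
    """Truncated-SVD scores of unit-variance-scaled Pearson residuals.

    Residuals of the highly variable genes are scaled to unit variance
    without mean-centering, then decomposed; component signs are fixed so
    the largest-magnitude gene loading of each component is positive.
    """
    hvgs = list(hvgs)
    if not hvgs:
        raise ValidationError("hvgs must be non-empty")
    if n_comps >= min(dataset.n_cells, len(hvgs)):
        raise ValidationError(
            f"n_comps={n_comps} must be below min(n_cells, n_hvgs)="
            f"{min(dataset.n_cells, len(hvgs))}"
        )
    cols = dataset.gene_indices(hvgs)
    sub = sp.csr_matrix(dataset.counts)[:, cols]
    resid = pearson_residuals(sub, theta=theta, clip=float(np.sqrt(dataset.n_cells)))
    std = np.sqrt((resid**2).mean(axis=0) - resid.mean(axis=0) ** 2)
    std[std == 0] = 1.0
    scaled = resid / std
    u, s, vt = np.linalg.svd(scaled, full_matrices=False)
    u, s, vt = u[:, :n_comps], s[:n_comps], vt[:n_comps]
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(vt[np.arange(n_comps), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    return u * s * flip


def knn_graph(embedding: np.ndarray, k: int = 15, metric: str = "euclidean") -> NeighborGraph:
    """Exact k-nearest neighbours per cell, self excluded.

    Ties in distance are broken by row index ascending, which makes the
    graph fully deterministic even with duplicated coordinates.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    x = np.asarray(embedding, dtype=np.float64)
    n = x.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be below n_cells={n}")
    if metric != "euclidean":
        raise ValidationError("only the euclidean metric is supported")
    indices = np.empty((n, k), dtype=np.int64)
    distances = np.empty((n, k), dtype=np.float64)
    sq = (x**2).sum(axis=1)
    chunk = max(1, int(2**22 // max(n, 1)))
    idx_all = np.arange(n)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] - 2 * (x[start:stop] @ x.T) + sq[None, :]
        np.maximum(d2, 0, out=d2)
        for r, i in enumerate(range(start, stop)):
            row = d2[r]
            order = np.lexsort((idx_all, row))
            order = order[order != i][:k]
            indices[i] = order
            distances[i] = np.sqrt(row[order])
    # enforce non-decreasing distances despite float sqrt rounding
    distances = np.maximum.accumulate(distances, axis=1)
    return NeighborGraph(k=k, indices=indices, distances=distances)


def graph_to_igraph(graph: NeighborGraph) -> igraph.Graph:
    """Undirected simple graph from the union of directed kNN edges."""
    n = graph.n_cells
    src = np.repeat(np.arange(n), graph.k)
    dst = graph.indices.ravel()
    edges = np.stack([np.minimum(src, dst), np.maximum(src, dst)], axis=1)
    edges = np.unique(edges, axis=0)
    g = igraph.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    return g


def cluster_leiden(
    graph: NeighborGraph, resolution: float = 1.0, seed: int = 0
) -> np.ndarray:
    """Leiden community detection (RBConfiguration objective) on the kNN graph."""
    g = graph_to_igraph(graph)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=np.int64)


def leiden_local(
    dataset: ExpressionDataset,
    labels: np.ndarray,
    selected_clusters: Sequence,
    n_hvgs: int = 5000,
    n_comps: int = 50,
    k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Re-cluster the cells of selected clusters, keeping all other labels.

    HVG selection, embedding and Leiden clustering are repeated on the
    selected cells only; new labels are namespaced as ``"<old>.<sub>"`` and
    cells outside the selection keep their labels verbatim.
    """
    labels = np.asarray(labels)
    label_set = set(np.unique(labels).tolist())
    missing = set(selected_clusters) - label_set
    if missing:
        raise ValidationError(f"selected clusters not in label set: {sorted(missing)}")
    mask = np.isin(labels, list(selected_clusters))
    n_sel = int(mask.sum())
    if n_sel <= k:
        raise ValidationError(
            f"selection of {n_sel} cells is too small for k={k} sub-graph"
        )
    sub = dataset.subset_cells(mask)
    # drop genes silent within the selection before residual ranking
    expressed = np.asarray((sub.counts > 0).sum(axis=0)).ravel() > 0
    sub = sub.subset_genes(expressed)
    hvgs = select_hvgs_pearson(sub, n_top=min(n_hvgs, sub.n_genes))
    comps = min(n_comps, min(n_sel, len(hvgs)) - 1)
    emb = embed_svd(sub, hvgs, n_comps=comps)
    sub_labels = cluster_leiden(knn_graph(emb, k=k), resolution=resolution, seed=seed)
    out = labels.astype(object).copy()
    sel_idx = np.flatnonzero(mask)
    for i, sub_lab in zip(sel_idx, sub_labels):
        out[i] = f"{labels[i]}.{sub_lab}"
    return out
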