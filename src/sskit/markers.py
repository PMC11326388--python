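"""Marker-gene scoring and gene-set expression scores.

Marker specificity follows the cosine-similarity construction: for gene g
and cluster c, lambda_gc is the cosine similarity between the gene's
normalized-expression vector over cells and the 0/1 indicator vector of the
cluster, and the marker score is

    score_gc = lambda_gc**2 / (lambda_gc**2 + mu * sum_{c' != c} lambda_gc'**2)

with score 0 for genes that are nowhere expressed.  ``mu`` penalizes genes
that also resemble other clusters.  Gene-set expression scores subtract a
control pool sampled from expression-level bins, so that scores are
centered under an exchangeable null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import ExpressionDataset, ValidationError

__all__ = [
    "GeneSignature",
    "MarkerTable",
    "cosg_scores",
    "top_markers",
    "select_reference_genes",
    "score_gene_set",
]


@dataclass
class GeneSignature:
    """Named ordered gene list with per-gene scores and provenance.

    ``provenance`` is per gene: ``"specific"`` (within-condition pattern),
    ``"differential"`` (cross-condition pattern) or ``"both"``.
    """

    name: str
    genes: list
    within_scores: Optional[list] = None
    cross_scores: Optional[list] = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("signature genes must be unique")
        for scores in (self.within_scores, self.cross_scores):
            if scores is not None and not np.all(np.isfinite(
                [s for s in scores if s is not None]
            )):
                raise ValidationError("signature scores must be finite")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class MarkerTable:
    """Genes x clusters marker scores plus consistent per-cluster rankings."""

    scores: pd.DataFrame  # index gene_id, columns cluster labels
    ranked_sets: dict  # cluster -> ordered gene id list (full ranking)
    params: dict


def _cluster_indicator(labels: np.ndarray):
    labels = np.asarray(labels)
    clusters, inverse = np.unique(labels, return_inverse=True)
    h = sp.csr_matrix(
        (np.ones(len(labels)), (np.arange(len(labels)), inverse)),
        shape=(len(labels), len(clusters)),
    )
    return clusters, h


def cosg_scores(
    dataset: ExpressionDataset,
    labels: np.ndarray,
    mu: float = 1.0,
    expressed_pct: Optional[float] = None,
) -> MarkerTable:
    """Cosine-similarity marker scores of every gene for every cluster.

    When ``expressed_pct`` is given, genes expressed in fewer than that
    fraction of a cluster's cells are scored 0 for that cluster and excluded
    from its ranking.  Requires at least two clusters and a normalized layer.
    """
    x = dataset.require_normalized()
    clusters, h = _cluster_indicator(labels)
    if len(clusters) < 2:
        raise ValidationError("marker scoring requires at least 2 clusters")
    gene_norm = np.sqrt(np.asarray(x.multiply(x).sum(axis=0)).ravel())
    size = np.asarray(h.sum(axis=0)).ravel()
    num = np.asarray((x.T @ h).todense())  # genes x clusters
    denom = np.outer(gene_norm, np.sqrt(size))
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    total = (lam**2).sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = lam**2 / (lam**2 + mu * (total - lam**2))
    score[~np.isfinite(score)] = 0.0
    score[lam == 0] = 0.0

    expressed_ok = np.ones_like(score, dtype=bool)
    if expressed_pct is not None:
        detected = (x > 0).astype(np.float64)
        frac = np.asarray((detected.T @ h).todense()) / np.maximum(size, 1)
        expressed_ok = frac >= expressed_pct
        score = np.where(expressed_ok, score, 0.0)

    gene_ids = dataset.gene_ids.astype(str)
    scores = pd.DataFrame(score, index=gene_ids, columns=clusters)
    ranked = {}
    for j, c in enumerate(clusters):
        keep = expressed_ok[:, j]
        order = np.lexsort((gene_ids, -score[:, j]))
        ranked[c] = [gene_ids[i] for i in order if keep[i]]
    return MarkerTable(
        scores=scores,
        ranked_sets=ranked,
        params={"mu": mu, "expressed_pct": expressed_pct},
    )


def top_markers(marker_table: MarkerTable, n: int) -> dict:
    """Top-``n`` marker signatures per cluster (ties by gene id ascending)."""
    if n < 1:
        raise ValidationError("n must be at least 1")
    out = {}
    for cluster, ranking in marker_table.ranked_sets.items():
        if n > len(ranking):
            warnings.warn(
                f"cluster {cluster!r}: requested {n} markers, only "
                f"{len(ranking)} rankable genes",
                stacklevel=2,
            )
        genes = ranking[:n]
        scores = [float(marker_table.scores.loc[g, cluster]) for g in genes]
        out[cluster] = GeneSignature(
            name=str(cluster),
            genes=genes,
            within_scores=scores,
            provenance=["specific"] * len(genes),
        )
    return out


def select_reference_genes(
    dataset: ExpressionDataset,
    labels: np.ndarray,
    n: int = 100,
    mu: float = 100.0,
    expressed_pct: float = 0.1,
) -> list:
    """Deduplicated, sorted union of per-cluster top-``n`` marker genes,
    with lowly expressed genes (below ``expressed_pct`` of the cluster's
    cells) removed before ranking."""
    table = cosg_scores(dataset, labels, mu=mu, expressed_pct=expressed_pct)
    union: set = set()
    for sig in top_markers(table, n).values():
        union |= set(sig.genes)
    if not union:
        raise ValidationError("reference gene selection produced an empty set")
    return sorted(union)


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size bins of genes by ascending mean expression (rank cut)."""
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(mean_expr), dtype=np.int64)
    bins[order] = np.arange(len(mean_expr)) * n_bins // len(mean_expr)
    return bins


def score_gene_set(
    dataset: ExpressionDataset,
    gene_set: Sequence[str],
    n_bins: int = 25,
    ctrl_size: Optional[int] = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell gene-set enrichment score against a binned control pool.

    Genes are binned by average normalized expression into ``n_bins``
    equal-size bins; for every bin touched by the set, ``ctrl_size`` control
    genes are sampled from that bin.  The score is the mean normalized
    expression of the set genes minus the mean over the control pool.
    """
    x = dataset.require_normalized()
    gene_ids = dataset.gene_ids.astype(str)
    present = [g for g in gene_set if g in set(gene_ids)]
    if not present:
        raise ValidationError("gene set has no overlap with dataset genes")
    set_idx = dataset.gene_indices(present)
    ctrl_size = ctrl_size or len(present)
    mean_expr = np.asarray(x.mean(axis=0)).ravel()
    bins = _expression_bins(mean_expr, n_bins)
    rng = np.random.default_rng(seed)
    ctrl_idx: list = []
    for b in np.unique(bins[set_idx]):
        pool = np.flatnonzero(bins == b)
        if len(pool) >= ctrl_size:
            ctrl_idx.extend(rng.choice(pool, size=ctrl_size, replace=False))
        else:
            ctrl_idx.extend(pool)  # bin smaller than ctrl_size: take it all
    ctrl_idx = np.asarray(ctrl_idx)
    set_mean = np.asarray(x[:, set_idx].mean(axis=1)).ravel()
    ctrl_mean = np.asarray(x[:, ctrl_idx].mean(axis=1)).ravel()
    return set_mean - ctrl_mean
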