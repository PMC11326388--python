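"""Marker-gene-guided dimensionality reduction and label transfer.

A shared embedding is built whose dimensions are marker-set expression
scores: one dimension per annotated reference cell type and one per
unsupervised cluster of the query (panel) modality.  Cells of both
modalities are scored on every marker set, landing them in a common
low-dimensional space where each axis reflects a biological identity.
Modalities are then aligned (moment matching by default, with a hook for
external integration methods) and reference labels are transferred to the
query with an RBF-kernel support vector machine with balanced class
weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .dataset import ExpressionDataset, ValidationError
from .markers import cosg_scores, score_gene_set, top_markers
from .preprocess import cluster_leiden, embed_svd, knn_graph, normalize_log, select_hvgs_pearson

__all__ = ["SharedEmbedding", "gdr_embed", "integrate_modalities", "transfer_labels"]

_MIN_SHARED_GENES = 50
_MIN_CLASS_SIZE = 5


@dataclass
class SharedEmbedding:
    """Cells x marker-set-score space shared by reference and query."""

    scores: np.ndarray  # (n_ref + n_query, D)
    dim_names: list
    modality: np.ndarray  # "ref" or "query" per cell
    ref_labels: np.ndarray  # per reference cell
    query_clusters: np.ndarray  # per query cell

    def __post_init__(self) -> None:
        if self.scores.shape[1] != len(self.dim_names):
            raise ValidationError("dim_names must match score columns")
        if self.scores.shape[0] != len(self.modality):
            raise ValidationError("modality must cover all cells")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError("embedding contains non-finite values")

    @property
    def ref_mask(self) -> np.ndarray:
        return self.modality == "ref"

    @property
    def query_mask(self) -> np.ndarray:
        return self.modality == "query"


def _renormalized(dataset: ExpressionDataset, cols: np.ndarray) -> ExpressionDataset:
    sub = dataset.subset_genes(cols)
    totals = np.asarray(sub.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        sub = sub.subset_cells(totals > 0)
        warnings.warn(
            f"dropped {int((totals == 0).sum())} cells with zero counts on the "
            "shared panel",
            stacklevel=2,
        )
    return normalize_log(sub)


def gdr_embed(
    reference: ExpressionDataset,
    ref_labels,
    query: ExpressionDataset,
    n_markers: int = 15,
    leiden_resolution: float = 1.0,
    cosg_mu: float = 1.0,
    knn_k: int = 15,
    score_n_bins: int = 25,
    seed: int = 0,
) -> SharedEmbedding:
    """Build the shared marker-set-score embedding.

    Both modalities are restricted to their shared genes and re-normalized;
    the query is clustered by Leiden; top-``n_markers`` marker sets are
    derived for every reference type and every query cluster; every set is
    scored in every cell of both modalities and the score columns stacked.
    """
    ref_ids = reference.gene_ids.astype(str)
    query_ids = set(query.gene_ids.astype(str))
    shared = [g for g in ref_ids if g in query_ids]
    if len(shared) < _MIN_SHARED_GENES:
        raise ValidationError(
            f"only {len(shared)} shared genes; at least {_MIN_SHARED_GENES} required"
        )
    ref = _renormalized(reference, reference.gene_indices(shared))
    qry = _renormalized(query, query.gene_indices(shared))
    ref_labels = np.asarray(ref_labels)
    if len(ref_labels) != ref.n_cells:
        raise ValidationError("ref_labels must align with reference cells")

    hvgs = select_hvgs_pearson(qry, n_top=min(2000, qry.n_genes))
    n_comps = min(50, min(qry.n_cells, len(hvgs)) - 1)
    emb = embed_svd(qry, hvgs, n_comps=n_comps)
    q_clusters = cluster_leiden(
        knn_graph(emb, k=knn_k), resolution=leiden_resolution, seed=seed
    )

    marker_sets: dict = {}
    ref_table = cosg_scores(ref, ref_labels, mu=cosg_mu)
    for c, sig in top_markers(ref_table, n_markers).items():
        marker_sets[f"ref:{c}"] = sig.genes
    qry_table = cosg_scores(qry, q_clusters, mu=cosg_mu)
    for c, sig in top_markers(qry_table, n_markers).items():
        marker_sets[f"query:{c}"] = sig.genes

    rng = np.random.default_rng(seed)
    dim_names, cols = [], []
    shared_set = set(shared)
    for name, genes in marker_sets.items():
        genes_in = [g for g in genes if g in shared_set]
        if not genes_in:
            warnings.warn(f"marker set {name!r} has no shared genes; dropped", stacklevel=2)
            continue
        set_seed = int(rng.integers(0, 2**31))
        col_ref = score_gene_set(ref, genes_in, n_bins=score_n_bins, seed=set_seed)
        col_qry = score_gene_set(qry, genes_in, n_bins=score_n_bins, seed=set_seed)
        dim_names.append(name)
        cols.append(np.concatenate([col_ref, col_qry]))
    scores = np.stack(cols, axis=1)
    modality = np.array(["ref"] * ref.n_cells + ["query"] * qry.n_cells)
    return SharedEmbedding(
        scores=scores,
        dim_names=dim_names,
        modality=modality,
        ref_labels=ref_labels,
        query_clusters=q_clusters,
    )


def integrate_modalities(
    embedding: SharedEmbedding,
    method: Union[str, Callable] = "moment_match",
) -> SharedEmbedding:
    """Remove modality-level location/scale differences per dimension.

    The default moment matcher standardizes each dimension within each
    modality and rescales to the pooled mean and standard deviation, so
    per-dimension modality means agree to numerical precision afterwards.
    A callable ``method(scores, modality) -> scores`` delegates to an
    external integration procedure under the same contract.
    """
    mods = np.unique(embedding.modality)
    if len(mods) < 2:
        warnings.warn("single modality present; integration is the identity", stacklevel=2)
        return embedding
    if callable(method):
        corrected = np.asarray(method(embedding.scores, embedding.modality))
        if corrected.shape != embedding.scores.shape:
            raise ValidationError("integration hook changed the embedding shape")
    elif method == "moment_match":
        corrected = embedding.scores.copy()
        pooled_mean = corrected.mean(axis=0)
        pooled_sd = corrected.std(axis=0)
        for m in mods:
            mask = embedding.modality == m
            mu = corrected[mask].mean(axis=0)
            sd = corrected[mask].std(axis=0)
            sd[sd == 0] = 1.0
            corrected[mask] = (corrected[mask] - mu) / sd * pooled_sd + pooled_mean
    else:
        raise ValidationError(f"unknown integration method {method!r}")
    return SharedEmbedding(
        scores=corrected,
        dim_names=list(embedding.dim_names),
        modality=embedding.modality,
        ref_labels=embedding.ref_labels,
        query_clusters=embedding.query_clusters,
    )


def transfer_labels(
    embedding: SharedEmbedding,
    C: float = 1.0,
    gamma: Union[str, float] = "scale",
    seed: int = 0,
) -> pd.DataFrame:
    """Predict query cell types with an RBF-kernel SVM trained on the
    reference cells' embedding coordinates.

    Class weights are inversely proportional to class frequency; reference
    classes with fewer than 5 cells are dropped with a warning.  Returns a
    table of predicted types and the winning decision score per query cell.
    """
    ref_mask = embedding.ref_mask
    labels = embedding.ref_labels
    counts = pd.Series(labels).value_counts()
    small = counts[counts < _MIN_CLASS_SIZE].index.tolist()
    if small:
        warnings.warn(f"dropping reference classes with <5 cells: {small}", stacklevel=2)
    keep = ~pd.Series(labels).isin(small).to_numpy()
    if pd.Series(labels[keep]).nunique() < 2:
        raise ValidationError("need at least 2 reference classes with >=5 cells")
    clf = SVC(
        kernel="rbf", C=C, gamma=gamma, class_weight="balanced",
        random_state=int(seed), decision_function_shape="ovr",
    )
    clf.fit(embedding.scores[ref_mask][keep], labels[keep])
    xq = embedding.scores[embedding.query_mask]
    pred = clf.predict(xq)
    dec = clf.decision_function(xq)
    if dec.ndim == 1:  # binary: signed distance to the separating surface
        score = np.abs(dec)
    else:
        score = dec.max(axis=1)
    return pd.DataFrame({"predicted_type": pred, "decision_score": score})
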