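"""Core in-memory containers shared by every analysis stage.

The central object is :class:`ExpressionDataset`, a light cells x genes
container holding raw counts (sparse), an optional normalized layer,
per-cell and per-gene metadata tables, named embeddings and an optional
k-nearest-neighbour graph.  All matrices are cells-in-rows and
genes-in-columns; indices are 0-based internally, identifiers live in the
metadata tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["ExpressionDataset", "NeighborGraph", "RunConfig"]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


@dataclass
class NeighborGraph:
    """Exact k-nearest-neighbour structure over the cells of a dataset.

    Attributes
    ----------
    k : int
        Number of neighbours per cell (self excluded).
    indices : (n_cells, k) int array
        Row indices of each cell's neighbours, sorted by ascending distance.
    distances : (n_cells, k) float array
        Distances to the neighbours, row-aligned with ``indices``.
    """

    k: int
    indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.k <= 0:
            raise ValidationError("k must be positive")
        n = self.indices.shape[0]
        if self.indices.shape != (n, self.k) or self.distances.shape != (n, self.k):
            raise ValidationError(
                f"indices/distances must be (n_cells, k); got {self.indices.shape} "
                f"and {self.distances.shape} for k={self.k}"
            )
        if np.any((self.indices < 0) | (self.indices >= n)):
            raise ValidationError("neighbor indices out of range")
        rows = np.arange(n)[:, None]
        if np.any(self.indices == rows):
            raise ValidationError("self-index present in neighbor rows")
        if np.any(np.diff(self.distances, axis=1) < 0):
            raise ValidationError("neighbor rows must be sorted by ascending distance")
        if np.any(self.distances < 0):
            raise ValidationError("negative neighbor distances")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]


@dataclass
class ExpressionDataset:
    """Cells x genes expression container.

    Parameters
    ----------
    counts : sparse matrix
        Non-negative integer counts, cells in rows.
    cell_table : DataFrame
        Per-cell records; must contain a unique ``cell_id`` column.  Optional
        columns used downstream: ``condition``, ``region``, ``modality``,
        ``cluster``, ``layer``, ``x``, ``y``, ``doublet_score``, ``cell_type``.
    gene_table : DataFrame
        Per-gene records; must contain a unique ``gene_id`` column plus
        boolean ``mito``/``ribo`` flags (added automatically if missing).
    normalized : sparse or dense matrix, optional
        Normalized expression layer, same shape as ``counts``.
    embeddings : dict of name -> (n_cells, d) arrays
    neighbor_graph : NeighborGraph, optional
    """

    counts: sp.spmatrix
    cell_table: pd.DataFrame
    gene_table: pd.DataFrame
    normalized: Optional[sp.spmatrix] = None
    embeddings: dict = field(default_factory=dict)
    neighbor_graph: Optional[NeighborGraph] = None

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts contain negative entries")
        n_cells, n_genes = self.counts.shape
        if "cell_id" not in self.cell_table.columns:
            raise ValidationError("cell_table must contain a 'cell_id' column")
        if "gene_id" not in self.gene_table.columns:
            raise ValidationError("gene_table must contain a 'gene_id' column")
        if len(self.cell_table) != n_cells:
            raise ValidationError(
                f"cell_table has {len(self.cell_table)} rows but counts has "
                f"{n_cells} cells"
            )
        if len(self.gene_table) != n_genes:
            raise ValidationError(
                f"gene_table has {len(self.gene_table)} rows but counts has "
                f"{n_genes} genes"
            )
        if self.cell_table["cell_id"].duplicated().any():
            raise ValidationError("duplicate cell_id values")
        if self.gene_table["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id values")
        self.cell_table = self.cell_table.reset_index(drop=True)
        self.gene_table = self.gene_table.reset_index(drop=True)
        if "mito" not in self.gene_table.columns or "ribo" not in self.gene_table.columns:
            gid = self.gene_table["gene_id"].astype(str)
            self.gene_table = self.gene_table.assign(
                mito=gid.str.startswith("mt-"),
                ribo=gid.str.startswith(("Rpl", "Rps")),
            )
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValidationError("normalized layer shape mismatch")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_ids(self) -> np.ndarray:
        return self.gene_table["gene_id"].to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_table["cell_id"].to_numpy()

    def gene_indices(self, gene_ids) -> np.ndarray:
        """Map gene identifiers to 0-based column indices (error on misses)."""
        lookup = pd.Index(self.gene_table["gene_id"])
        idx = lookup.get_indexer(list(gene_ids))
        if np.any(idx < 0):
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes not present in dataset: {missing[:10]}")
        return idx

    def require_normalized(self) -> sp.csr_matrix:
        if self.normalized is None:
            raise ValidationError("dataset has no normalized layer; run normalize_log")
        return sp.csr_matrix(self.normalized)

    def subset_cells(self, mask_or_idx) -> "ExpressionDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionDataset(
            counts=self.counts[idx],
            cell_table=self.cell_table.iloc[idx].reset_index(drop=True),
            gene_table=self.gene_table.copy(),
            normalized=None if self.normalized is None else sp.csr_matrix(self.normalized)[idx],
            embeddings={k: v[idx] for k, v in self.embeddings.items()},
            neighbor_graph=None,  # graph indices are invalid after subsetting
        )

    def subset_genes(self, mask_or_idx) -> "ExpressionDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionDataset(
            counts=self.counts[:, idx],
            cell_table=self.cell_table.copy(),
            gene_table=self.gene_table.iloc[idx].reset_index(drop=True),
            normalized=None if self.normalized is None else sp.csr_matrix(self.normalized)[:, idx],
            embeddings=dict(self.embeddings),
            neighbor_graph=self.neighbor_graph,
        )

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            counts=self.counts.copy(),
            cell_table=self.cell_table.copy(),
            gene_table=self.gene_table.copy(),
            normalized=None if self.normalized is None else self.normalized.copy(),
            embeddings={k: v.copy() for k, v in self.embeddings.items()},
            neighbor_graph=self.neighbor_graph,
        )

    def equals(self, other: "ExpressionDataset") -> bool:
        """Equality of counts, metadata and flags (layers/embeddings ignored)."""
        if self.counts.shape != other.counts.shape:
            return False
        if (self.counts != other.counts).nnz != 0:
            return False
        cols = sorted(set(self.cell_table.columns) | set(other.cell_table.columns))
        gcols = sorted(set(self.gene_table.columns) | set(other.gene_table.columns))
        try:
            pd.testing.assert_frame_equal(
                self.cell_table.reindex(columns=cols),
                other.cell_table.reindex(columns=cols),
                check_dtype=False,
            )
            pd.testing.assert_frame_equal(
                self.gene_table.reindex(columns=gcols),
                other.gene_table.reindex(columns=gcols),
                check_dtype=False,
            )
        except AssertionError:
            return False
        return True


@dataclass
class RunConfig:
    """Flat bag of stage parameters plus the master seed.

    Every stochastic operation derives its own child seed from ``seed`` via
    :meth:`child_seed`, so a single integer reproduces a full pipeline run.
    """

    seed: int = 0
    # QC
    max_counts: int = 15000
    min_genes: int = 200
    max_genes: int = 4000
    max_mito: float = 0.05
    max_ribo: float = 0.05
    max_doublet: float = 0.25
    # normalization / embedding
    target_sum: float = 10000.0
    n_hvgs: int = 5000
    n_comps: int = 50
    knn_k: int = 15
    leiden_resolution: float = 1.0
    # markers
    cosg_mu: float = 1.0
    n_top_markers: int = 15
    ref_n_markers: int = 100
    ref_mu: float = 100.0
    expressed_pct: float = 0.1
    score_n_bins: int = 25
    # emergene
    emergene_k: int = 30
    n_top_within: int = 10
    n_top_cross: int = 90
    n_control_sets: int = 10000
    n_bins_mean: int = 10
    n_bins_var: int = 10
    percentile: float = 50.0
    alpha: float = 0.05
    # gdr
    gdr_n_markers: int = 15
    svm_c: float = 1.0
    # tamap
    tamap_epsilon: float = 0.05
    # spatial
    layers_k: int = 5

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        ss = np.random.SeedSequence([self.seed, abs(hash_stage(stage))])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def hash_stage(stage: str) -> int:
    """Stable (non-salted) string hash used for per-stage seed derivation."""
    h = 2166136261
    for ch in stage.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h
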