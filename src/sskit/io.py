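"""Readers and writers for the on-disk formats used by the pipeline.

Counts travel as Matrix Market coordinate files (cells in rows, genes in
columns) next to delimited gene and cell tables; results are written as
tab-delimited tables plus a JSON manifest recording the configuration and
seeds of the run.  Delimiters of input tables (TSV vs CSV) are sniffed from
the header line.
"""

from __future__ import annotations

import json
import os
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .dataset import ExpressionDataset, RunConfig, ValidationError

__all__ = ["read_dataset", "write_dataset", "read_table", "write_results"]

_VERSION = "0.1.0"


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_table(path) -> pd.DataFrame:
    """Read a delimited table with a header row, sniffing TSV vs CSV."""
    return pd.read_csv(path, sep=_sniff_sep(path))


def read_dataset(matrix_path, genes_path, cells_path) -> ExpressionDataset:
    """Assemble an :class:`ExpressionDataset` from a Matrix Market triplet.

    ``matrix_path`` holds cells x genes counts in coordinate format;
    ``genes_path`` / ``cells_path`` are delimited tables with ``gene_id`` /
    ``cell_id`` columns.  Mitochondrial genes are flagged by the ``mt-``
    prefix and ribosomal genes by ``Rpl``/``Rps`` prefixes.
    """
    counts = sp.csr_matrix(scipy.io.mmread(matrix_path))
    if counts.nnz and counts.data.min() < 0:
        raise ValidationError(f"negative entries in count matrix {matrix_path}")
    genes = read_table(genes_path)
    cells = read_table(cells_path)
    if "gene_id" not in genes.columns:
        raise ValidationError(f"{genes_path}: missing 'gene_id' column")
    if "cell_id" not in cells.columns:
        raise ValidationError(f"{cells_path}: missing 'cell_id' column")
    if len(cells) != counts.shape[0]:
        raise ValidationError(
            f"{cells_path}: {len(cells)} cells but matrix has {counts.shape[0]} rows"
        )
    if len(genes) != counts.shape[1]:
        raise ValidationError(
            f"{genes_path}: {len(genes)} genes but matrix has {counts.shape[1]} columns"
        )
    gid = genes["gene_id"].astype(str)
    genes = genes.assign(
        mito=gid.str.startswith("mt-"), ribo=gid.str.startswith(("Rpl", "Rps"))
    )
    return ExpressionDataset(counts=counts, cell_table=cells, gene_table=genes)


def write_dataset(dataset: ExpressionDataset, out_dir) -> dict:
    """Write a dataset as matrix.mtx + genes.tsv + cells.tsv; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(dataset.counts), field="integer")
    dataset.gene_table.to_csv(paths["genes"], sep="\t", index=False)
    dataset.cell_table.to_csv(paths["cells"], sep="\t", index=False)
    return {k: str(v) for k, v in paths.items()}


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> dict:
    """Write named result tables as TSV plus a JSON run manifest.

    Floats are written at full ``repr`` precision so a write/read round trip
    is bit-exact.  Returns the manifest dict (also written to
    ``manifest.json``).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValidationError(f"cannot create output directory {out}: {exc}") from exc
    if not os.access(out, os.W_OK):
        raise ValidationError(f"output directory {out} is not writable")
    entries = []
    for name, table in tables.items():
        path = out / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        entries.append(
            {"name": name, "path": path.name, "n_rows": int(len(table)),
             "n_cols": int(table.shape[1])}
        )
    manifest = {
        "version": _VERSION,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": config.to_dict() if config is not None else None,
        "tables": entries,
        "created": datetime.now(timezone.utc).isoformat(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
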