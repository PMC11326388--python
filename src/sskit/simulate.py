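"""Synthetic data generators emulating the study designs the pipeline targets.

The generators produce (a) multi-type negative-binomial count matrices with
planted marker genes, (b) a reduced shared gene panel with a modality shift
(imaging-panel-like), (c) two-condition designs with subtype ablation,
proportion scaling and gene-program shifts, and (d) a layered spatial
scaffold of excitatory cells with interleaved interneurons.

Counts follow a negative binomial parameterized by mean ``mu`` and
dispersion ``theta`` (variance ``mu + mu**2/theta``), with unit-mean
per-cell library-size factors (LogNormal, sigma 0.3).  All generators are
bitwise reproducible under a fixed seed.
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
    "CellTypeSpec",
    "PopulationSpec",
    "ConditionEffect",
    "simulate_reference",
    "simulate_query_panel",
    "simulate_conditions",
    "simulate_spatial",
    "fezf2like_reference_spec",
    "fezf2like_effects",
    "null_spec",
    "default_program_genes",
]

_SIZE_FACTOR_SIGMA = 0.3


@dataclass
class CellTypeSpec:
    """One population component: name, abundance, planted markers, layer."""

    name: str
    proportion: float
    marker_genes: Sequence[int] = ()
    marker_fold: float = 1.0
    layer: str = "L1"
    cell_class: str = "excitatory"  # or "interneuron"


@dataclass
class PopulationSpec:
    """Mixture of negative-binomial cell types over a shared gene space.

    Per-gene baseline means are drawn once per spec as
    ``nb_mean * LogNormal(-gene_mean_sigma**2/2, gene_mean_sigma)`` so that
    genes span expression levels the way real transcriptomes do while the
    average baseline stays at ``nb_mean``; set ``gene_mean_sigma=0`` for a
    fully exchangeable gene pool.
    """

    cell_types: list
    n_cells: int = 3000
    n_genes: int = 1500
    nb_mean: float = 0.5
    nb_dispersion: float = 2.0
    gene_mean_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(t.proportion for t in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"type proportions sum to {total}, not 1")
        if self.nb_mean <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("nb_mean and nb_dispersion must be positive")
        seen: set = set()
        for t in self.cell_types:
            idx = np.asarray(list(t.marker_genes), dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_genes):
                raise ValidationError(f"marker indices of {t.name} outside n_genes")
            if t.marker_fold <= 0:
                raise ValidationError("marker_fold must be positive")
            overlap = seen & set(idx.tolist())
            if overlap:
                warnings.warn(
                    f"marker genes shared between types: {sorted(overlap)[:5]}...",
                    stacklevel=2,
                )
            seen |= set(idx.tolist())

    def type_names(self) -> list:
        return [t.name for t in self.cell_types]


@dataclass
class ConditionEffect:
    """A single perturbation applied to the mutant condition.

    ``kind`` is one of ``ablate_type`` (remove the type; ``factor`` forced
    to 0), ``scale_proportion`` (multiply the type's abundance by ``factor``
    then renormalize), or ``program_shift`` (multiply the means of
    ``program_genes`` by ``program_fold`` in cells of the target type).
    """

    kind: str
    target_type: str
    factor: float = 1.0
    program_genes: Optional[Sequence[int]] = None
    program_fold: float = 1.0

    def __post_init__(self) -> None:
        kinds = {"ablate_type", "scale_proportion", "program_shift"}
        if self.kind not in kinds:
            raise ValidationError(f"unknown effect kind {self.kind!r}")
        if self.kind == "ablate_type":
            self.factor = 0.0
        elif self.factor == 0:
            raise ValidationError("factor=0 only allowed with ablate_type")
        if self.kind == "program_shift" and not self.program_genes:
            raise ValidationError("program_shift requires program_genes")


def _base_gene_means(spec: PopulationSpec) -> np.ndarray:
    """Per-gene baseline means, fixed by the spec's seed (condition-shared)."""
    if spec.gene_mean_sigma == 0:
        return np.full(spec.n_genes, spec.nb_mean)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x67656E65]))
    s = spec.gene_mean_sigma
    return spec.nb_mean * rng.lognormal(-0.5 * s * s, s, size=spec.n_genes)


def _type_means(spec: PopulationSpec) -> np.ndarray:
    """(n_types, n_genes) mean matrix with marker folds applied."""
    means = np.tile(_base_gene_means(spec), (len(spec.cell_types), 1))
    for i, t in enumerate(spec.cell_types):
        idx = np.asarray(list(t.marker_genes), dtype=int)
        if idx.size:
            means[i, idx] *= t.marker_fold
    return means


def _sample_counts(means_per_cell: np.ndarray, theta: float, rng) -> np.ndarray:
    # Gamma-Poisson mixture == NB(mean mu, dispersion theta)
    lam = rng.gamma(shape=theta, scale=means_per_cell / theta)
    return rng.poisson(lam)


def _simulate(
    spec: PopulationSpec,
    n_cells: int,
    proportions: np.ndarray,
    type_subset: list,
    program_shifts: dict,
    rng,
    id_prefix: str = "c",
) -> ExpressionDataset:
    type_idx = rng.choice(len(type_subset), size=n_cells, p=proportions)
    # unit-mean size factors keep nb_mean the true per-gene expectation
    size_factors = rng.lognormal(
        mean=-0.5 * _SIZE_FACTOR_SIGMA**2, sigma=_SIZE_FACTOR_SIGMA, size=n_cells
    )
    base_means = _type_means(spec)
    counts = np.empty((n_cells, spec.n_genes), dtype=np.int64)
    for j, t in enumerate(type_subset):
        rows = np.flatnonzero(type_idx == j)
        if rows.size == 0:
            continue
        mu = base_means[spec.type_names().index(t.name)].copy()
        if t.name in program_shifts:
            genes, fold = program_shifts[t.name]
            mu[np.asarray(list(genes), dtype=int)] *= fold
        counts[rows] = _sample_counts(
            size_factors[rows, None] * mu[None, :], spec.nb_dispersion, rng
        )
    width = len(str(max(n_cells - 1, 1)))
    cell_table = pd.DataFrame(
        {
            "cell_id": [f"{id_prefix}{i:0{width}d}" for i in range(n_cells)],
            "cell_type": [type_subset[j].name for j in type_idx],
            "layer": [type_subset[j].layer for j in type_idx],
            "cell_class": [type_subset[j].cell_class for j in type_idx],
        }
    )
    gene_table = pd.DataFrame(
        {"gene_id": [f"g{i:04d}" for i in range(spec.n_genes)]}
    )
    return ExpressionDataset(
        counts=sp.csr_matrix(counts), cell_table=cell_table, gene_table=gene_table
    )


def simulate_reference(spec: PopulationSpec) -> ExpressionDataset:
    """Draw a multi-type NB reference dataset according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    props = np.array([t.proportion for t in spec.cell_types])
    return _simulate(spec, spec.n_cells, props / props.sum(), spec.cell_types, {}, rng)


def simulate_query_panel(
    reference: ExpressionDataset,
    panel_genes: Sequence[str],
    capture_rate: float,
    modality_scale: float,
    seed: int,
) -> ExpressionDataset:
    """Restrict to a gene panel with binomial thinning and a modality scale.

    Counts are binomially thinned at ``capture_rate``, multiplied by
    ``modality_scale`` and re-rounded; the modality column is set to
    ``"panel"``.
    """
    panel_genes = list(panel_genes)
    if not panel_genes:
        raise ValidationError("empty gene panel")
    if not (0 < capture_rate <= 1):
        raise ValidationError("capture_rate must be in (0, 1]")
    if modality_scale <= 0:
        raise ValidationError("modality_scale must be positive")
    cols = reference.gene_indices(panel_genes)  # KeyError on missing genes
    rng = np.random.default_rng(seed)
    counts = sp.csr_matrix(reference.counts[:, cols], dtype=np.int64)
    data = rng.binomial(counts.data, capture_rate)
    data = np.rint(data * modality_scale).astype(np.int64)
    thinned = sp.csr_matrix((data, counts.indices, counts.indptr), shape=counts.shape)
    thinned.eliminate_zeros()
    cell_table = reference.cell_table.copy()
    cell_table["modality"] = "panel"
    gene_table = reference.gene_table.iloc[cols].reset_index(drop=True)
    return ExpressionDataset(counts=thinned, cell_table=cell_table, gene_table=gene_table)


def simulate_conditions(
    reference_spec: PopulationSpec,
    effects: Sequence[ConditionEffect],
    seed: int,
    n_cells_per_condition: Optional[int] = None,
) -> ExpressionDataset:
    """Draw a paired control/mutant dataset under a list of effects.

    The control condition follows ``reference_spec`` unchanged; the mutant
    applies each effect (type ablation, proportion scaling, gene-program
    shift) with proportions renormalized after abundance edits.  The
    ``condition`` column is ``ctrl``/``mut``.  With an empty effects list
    the two conditions are statistically exchangeable.
    """
    names = reference_spec.type_names()
    for eff in effects:
        if eff.target_type not in names:
            raise ValidationError(f"effect targets unknown type {eff.target_type!r}")
        if eff.kind == "program_shift":
            idx = np.asarray(list(eff.program_genes), dtype=int)
            if idx.min() < 0 or idx.max() >= reference_spec.n_genes:
                raise ValidationError("program gene indices outside n_genes")
    n_each = n_cells_per_condition or reference_spec.n_cells // 2
    rng = np.random.default_rng(seed)

    props = {t.name: t.proportion for t in reference_spec.cell_types}
    kept = list(reference_spec.cell_types)
    program_shifts: dict = {}
    for eff in effects:
        if eff.kind == "ablate_type":
            kept = [t for t in kept if t.name != eff.target_type]
        elif eff.kind == "scale_proportion":
            props[eff.target_type] *= eff.factor
        else:
            program_shifts[eff.target_type] = (eff.program_genes, eff.program_fold)
    if not kept:
        raise ValidationError("all cell types ablated; cannot renormalize")
    mut_props = np.array([props[t.name] for t in kept])
    if mut_props.sum() <= 0:
        raise ValidationError("mutant proportions sum to zero; cannot renormalize")
    mut_props = mut_props / mut_props.sum()

    ctrl_props = np.array([t.proportion for t in reference_spec.cell_types])
    ctrl = _simulate(
        reference_spec, n_each, ctrl_props / ctrl_props.sum(),
        reference_spec.cell_types, {}, rng, id_prefix="ctrl-",
    )
    mut = _simulate(
        reference_spec, n_each, mut_props, kept, program_shifts, rng, id_prefix="mut-",
    )
    counts = sp.vstack([ctrl.counts, mut.counts]).tocsr()
    cell_table = pd.concat(
        [ctrl.cell_table.assign(condition="ctrl"), mut.cell_table.assign(condition="mut")],
        ignore_index=True,
    )
    return ExpressionDataset(
        counts=counts, cell_table=cell_table, gene_table=ctrl.gene_table
    )


def simulate_spatial(
    cell_table: pd.DataFrame,
    layer_bands: Sequence[tuple],
    jitter: float,
    seed: int,
    width: float = 1.0,
) -> pd.DataFrame:
    """Place cells on a layered 2-D scaffold.

    ``layer_bands`` is a list of ``(label, y_min, y_max)`` with
    non-overlapping vertical extents.  Excitatory cells are placed uniformly
    within their band; interneurons uniformly within their true band plus
    Gaussian vertical jitter of standard deviation ``jitter``.  x is uniform
    on ``[0, width]``.
    """
    bands = sorted(layer_bands, key=lambda b: b[1])
    for label, lo, hi in bands:
        if hi <= lo:
            raise ValidationError(f"band {label!r} has non-positive height")
    for (l1, _, hi1), (l2, lo2, _) in zip(bands, bands[1:]):
        if hi1 > lo2:
            raise ValidationError(f"bands {l1!r} and {l2!r} overlap")
    band_map = {label: (lo, hi) for label, lo, hi in bands}
    missing = set(cell_table["layer"].unique()) - set(band_map)
    if missing:
        raise ValidationError(f"layers without a band: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    n = len(cell_table)
    lo = np.array([band_map[l][0] for l in cell_table["layer"]])
    hi = np.array([band_map[l][1] for l in cell_table["layer"]])
    y = rng.uniform(lo, hi)
    is_in = (cell_table.get("cell_class", pd.Series(["excitatory"] * n)) == "interneuron").to_numpy()
    if jitter > 0 and is_in.any():
        y[is_in] += rng.normal(0.0, jitter, size=int(is_in.sum()))
    x = rng.uniform(0.0, width, size=n)
    return pd.DataFrame(
        {
            "cell_id": cell_table["cell_id"].to_numpy(),
            "x": x,
            "y": y,
            "layer": cell_table["layer"].to_numpy(),
            "cell_class": np.where(is_in, "interneuron", "excitatory"),
        }
    )


# -- presets -----------------------------------------------------------------


def fezf2like_reference_spec(
    n_cells: int = 3000,
    n_genes: int = 1500,
    n_markers_per_type: int = 10,
    marker_fold: float = 8.0,
    seed: int = 0,
    proportions: Optional[dict] = None,
) -> PopulationSpec:
    """Eight-type cortical population: five excitatory classes in layers
    L2/3-L6 plus three interneuron classes, with disjoint planted marker
    blocks of ``n_markers_per_type`` genes at ``marker_fold``."""
    base = [
        ("L23IT", 0.20, "L2/3", "excitatory"),
        ("L45IT", 0.15, "L4", "excitatory"),
        ("L5PT", 0.07, "L5", "excitatory"),
        ("L5NP", 0.05, "L5", "excitatory"),
        ("L6IT", 0.13, "L6", "excitatory"),
        ("PVALB", 0.15, "L5", "interneuron"),
        ("SST", 0.15, "L5", "interneuron"),
        ("VIP", 0.10, "L2/3", "interneuron"),
    ]
    if proportions is not None:
        base = [(n, proportions.get(n, p), lay, cls) for n, p, lay, cls in base]
        total = sum(p for _, p, _, _ in base)
        base = [(n, p / total, lay, cls) for n, p, lay, cls in base]
    types = [
        CellTypeSpec(
            name=name,
            proportion=prop,
            marker_genes=range(i * n_markers_per_type, (i + 1) * n_markers_per_type),
            marker_fold=marker_fold,
            layer=layer,
            cell_class=cls,
        )
        for i, (name, prop, layer, cls) in enumerate(base)
    ]
    return PopulationSpec(
        cell_types=types, n_cells=n_cells, n_genes=n_genes, seed=seed
    )


def default_program_genes(spec: PopulationSpec, n: int = 50) -> list:
    """``n`` gene indices free of planted markers, for program-shift effects."""
    used = set()
    for t in spec.cell_types:
        used |= set(int(i) for i in t.marker_genes)
    free = [i for i in range(spec.n_genes) if i not in used]
    if len(free) < n:
        raise ValidationError("not enough marker-free genes for a program")
    return free[:n]


def fezf2like_effects(
    spec: PopulationSpec,
    program_fold: float = 4.0,
    n_program_genes: int = 50,
    shift_target: str = "SST",
) -> list:
    """Knockout-like design: loss of L5 PT and NP types, expansion of L6 IT,
    and a gene-program shift in one interneuron subtype."""
    return [
        ConditionEffect(kind="ablate_type", target_type="L5PT"),
        ConditionEffect(kind="ablate_type", target_type="L5NP"),
        ConditionEffect(kind="scale_proportion", target_type="L6IT", factor=2.0),
        ConditionEffect(
            kind="program_shift",
            target_type=shift_target,
            program_genes=default_program_genes(spec, n_program_genes),
            program_fold=program_fold,
        ),
    ]


def null_spec(n_cells: int = 2000, n_genes: int = 1500, seed: int = 0) -> PopulationSpec:
    """Single homogeneous population: the exchangeable null for calibration."""
    return PopulationSpec(
        cell_types=[CellTypeSpec(name="uniform", proportion=1.0)],
        n_cells=n_cells,
        n_genes=n_genes,
        gene_mean_sigma=0.0,
        seed=seed,
    )
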