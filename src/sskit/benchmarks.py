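"""Desk-scale reference experiments exercising the pipeline end to end.

Each function regenerates its synthetic inputs, runs the relevant stages and
returns summary numbers: null calibration and planted-program power of the
cluster-free differential analysis, cross-modality label-transfer recovery,
marker recovery, layout closure, and small analytic checks.  The test suite
and the acceptance script both drive these harnesses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import emergene as em
from . import gdr
from . import markers as mk
from . import preprocess as pp
from . import simulate as sim
from . import spatial as spt
from . import tamap as tm
from .dataset import ExpressionDataset, RunConfig

__all__ = [
    "preprocess_basic",
    "emergene_null_run",
    "emergene_power_run",
    "gdr_recovery_run",
    "cosg_recovery_run",
    "exclusive_marker_score",
    "tamap_angle_closure",
    "oracle_equivalence",
    "ranksum_exact_example",
    "qc_toy",
    "qc_toy_survivors",
]


def preprocess_basic(data: ExpressionDataset, cfg: RunConfig):
    """Normalize, select HVGs, embed, build the kNN graph, cluster."""
    data = pp.normalize_log(data, target_sum=cfg.target_sum)
    hvgs = pp.select_hvgs_pearson(data, n_top=min(cfg.n_hvgs, data.n_genes))
    n_comps = min(cfg.n_comps, min(data.n_cells, len(hvgs)) - 1)
    embedding = pp.embed_svd(data, hvgs, n_comps=n_comps)
    graph = pp.knn_graph(embedding, k=cfg.knn_k)
    labels = pp.cluster_leiden(
        graph, resolution=cfg.leiden_resolution, seed=cfg.child_seed("leiden")
    )
    return data, embedding, graph, labels


def emergene_null_run(
    seed: int, n_cells: int = 2000, n_genes: int = 1500, n_control_sets: int = 1000
) -> dict:
    """Exchangeable null: one population randomly split into two conditions.

    Returns the per-cell rejection rate at alpha=0.05 and the number of
    flagged (cluster, condition) groups among those analyzed.
    """
    cfg = RunConfig(seed=seed, n_control_sets=n_control_sets)
    spec = sim.null_spec(n_cells=n_cells, n_genes=n_genes, seed=seed)
    data = sim.simulate_conditions(spec, [], seed=cfg.child_seed("sim"))
    data, embedding, graph, labels = preprocess_basic(data, cfg)
    res = em.run_emergene(data, embedding, graph, clusters=labels, config=cfg)
    rec = res.cluster_records
    return {
        "rejection_rate": float((res.p_cell < cfg.alpha).mean()),
        "n_flagged": int(rec.query("flagged and analyzed").shape[0]),
    }


def emergene_power_run(
    seed: int,
    n_cells: int = 2000,
    n_genes: int = 1500,
    n_control_sets: int = 1000,
    program_fold: float = 4.0,
    n_program_genes: int = 50,
    target: str = "SST",
) -> dict:
    """Planted program shift in one subtype of the eight-type population.

    Cluster records are grouped by true subtype and condition; returns the
    target group's significance summary, the worst off-target group, and the
    signature's recall of the planted program genes.
    """
    cfg = RunConfig(seed=seed, n_control_sets=n_control_sets)
    spec = sim.fezf2like_reference_spec(n_cells=n_cells, n_genes=n_genes, seed=seed)
    prog = sim.default_program_genes(spec, n_program_genes)
    effects = [
        sim.ConditionEffect(
            "program_shift", target, program_genes=prog, program_fold=program_fold
        )
    ]
    data = sim.simulate_conditions(spec, effects, seed=cfg.child_seed("sim"))
    data, embedding, graph, _ = preprocess_basic(data, cfg)
    truth = data.cell_table["cell_type"].to_numpy()
    res = em.run_emergene(data, embedding, graph, clusters=truth, config=cfg)
    rec = res.cluster_records.set_index("cluster")
    target_key = f"{target}|mut"
    tgt = rec.loc[target_key]
    off = rec.drop(index=target_key).query("analyzed")
    planted = {f"g{i:04d}" for i in prog}
    return {
        "target_frac_significant": float(tgt.frac_significant),
        "target_gliding_p": float(tgt.gliding_p),
        "target_flagged": bool(tgt.flagged),
        "off_target_flags": int(off.flagged.sum()),
        "max_off_target_frac": float(off.frac_significant.max()),
        "program_recall": len(planted & set(res.signature.genes)) / len(planted),
    }


def _macro_accuracy(truth: np.ndarray, pred: np.ndarray) -> float:
    return float(pd.Series(pred == truth).groupby(truth).mean().mean())


def gdr_recovery_run(
    seed: int,
    n_cells: int = 2000,
    n_genes: int = 1500,
    n_panel: int = 300,
    capture_rate: float = 0.5,
    modality_scale: float = 1.5,
) -> dict:
    """Label transfer onto a thinned, rescaled gene panel.

    Reference and query are independent draws of the eight-type population;
    returns macro accuracy (mean per-type recall) with and without modality
    integration.
    """
    cfg = RunConfig(seed=seed)
    spec = sim.fezf2like_reference_spec(n_cells=n_cells, n_genes=n_genes, seed=seed)
    ref = sim.simulate_reference(spec)
    spec_q = sim.fezf2like_reference_spec(
        n_cells=n_cells, n_genes=n_genes, seed=seed + 7000
    )
    panel = [f"g{i:04d}" for i in range(n_panel)]
    query = sim.simulate_query_panel(
        sim.simulate_reference(spec_q), panel, capture_rate, modality_scale,
        seed=cfg.child_seed("panel"),
    )
    embedding = gdr.gdr_embed(
        ref, ref.cell_table["cell_type"].to_numpy(), query,
        n_markers=cfg.gdr_n_markers, seed=cfg.child_seed("gdr"),
    )
    truth = query.cell_table["cell_type"].to_numpy()
    svm_seed = cfg.child_seed("svm")
    with_int = gdr.transfer_labels(
        gdr.integrate_modalities(embedding), C=cfg.svm_c, seed=svm_seed
    )["predicted_type"].to_numpy()
    without = gdr.transfer_labels(embedding, C=cfg.svm_c, seed=svm_seed)[
        "predicted_type"
    ].to_numpy()
    return {
        "macro_accuracy": _macro_accuracy(truth, with_int),
        "macro_accuracy_no_integration": _macro_accuracy(truth, without),
    }


def cosg_recovery_run(seed: int, n_cells: int = 2000, n_genes: int = 1500) -> dict:
    """Recall of planted fold-8 markers within the top-15 marker calls."""
    spec = sim.fezf2like_reference_spec(n_cells=n_cells, n_genes=n_genes, seed=seed)
    data = pp.normalize_log(sim.simulate_reference(spec))
    labels = data.cell_table["cell_type"].to_numpy()
    sigs = mk.top_markers(mk.cosg_scores(data, labels), 15)
    recalls = []
    for t in spec.cell_types:
        planted = {f"g{i:04d}" for i in t.marker_genes}
        recalls.append(len(planted & set(sigs[t.name].genes)) / len(planted))
    return {"mean_recall": float(np.mean(recalls)), "min_recall": float(np.min(recalls))}


def exclusive_marker_score() -> float:
    """Marker score of a gene expressed uniformly in exactly one cluster."""
    import scipy.sparse as sp

    norm = np.zeros((6, 2))
    norm[:3, 0] = 2.0
    norm[:, 1] = 1.0
    ds = ExpressionDataset(
        counts=sp.csr_matrix(np.ones((6, 2), dtype=int)),
        cell_table=pd.DataFrame({"cell_id": [f"c{i}" for i in range(6)]}),
        gene_table=pd.DataFrame({"gene_id": ["marker", "house"]}),
        normalized=sp.csr_matrix(norm),
    )
    table = mk.cosg_scores(ds, np.array(["a"] * 3 + ["b"] * 3))
    return float(table.scores.loc["marker", "a"])


def tamap_angle_closure(n: int = 1000, seed: int = 0) -> float:
    """Max |sum(angles) - 360| over random similarity inputs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n):
        vals = rng.uniform(-10, 10, size=6)
        layout = tm.tamap_layout(vals[:3], vals[3:])
        worst = max(worst, abs(float(layout.angles.sum()) - 360.0))
    return worst


def ranksum_exact_example() -> float:
    """Two-sided exact rank-sum p for {1,2,3} vs {4,5,6}."""
    values = pd.DataFrame({"t": [1, 2, 3, 4, 5, 6]})
    out = spt.rank_sum_compare(values, ["a"] * 3 + ["b"] * 3, "a", "b")
    return float(out.iloc[0].p)


# -- brute-force oracles ------------------------------------------------------


def _cols_cos(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = (a * b).sum(axis=0)
    den = np.linalg.norm(a, axis=0) * np.linalg.norm(b, axis=0)
    return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)


def oracle_equivalence(seed: int = 0) -> dict:
    """Max deviation of the fast paths from dense brute-force recomputation.

    Covers kNN graph construction, local diffusion, the within-condition
    pattern score, the cross-condition deviation score, and layer
    assignment, on instances of 150-1000 elements.
    """
    rng = np.random.default_rng(seed)
    out = {}

    # kNN graph vs exhaustive sort
    x = rng.normal(size=(300, 5))
    g = pp.knn_graph(x, k=9)
    knn_idx_err = 0
    knn_dist_err = 0.0
    for i in range(300):
        d = np.linalg.norm(x - x[i], axis=1)
        order = [j for j in sorted(range(300), key=lambda j: (d[j], j)) if j != i][:9]
        knn_idx_err += int(not np.array_equal(g.indices[i], order))
        knn_dist_err = max(knn_dist_err, float(np.abs(g.distances[i] - d[order]).max()))
    out["knn_index_mismatches"] = knn_idx_err
    out["knn_distance_error"] = knn_dist_err

    # diffusion + pattern score vs dense loops
    norm = rng.random((200, 40))
    emb = rng.normal(size=(200, 4))
    graph = pp.knn_graph(emb, k=8)
    dense_local = np.stack([norm[graph.indices[i]].mean(axis=0) for i in range(200)])
    import scipy.sparse as sp

    fast_local = em.diffuse_local(sp.csr_matrix(norm), graph).toarray()
    out["diffuse_local_error"] = float(np.abs(fast_local - dense_local).max())

    ds = ExpressionDataset(
        counts=sp.csr_matrix(np.ones((200, 40), dtype=int)),
        cell_table=pd.DataFrame(
            {"cell_id": [f"c{i}" for i in range(200)],
             "condition": ["ctrl", "mut"] * 100}
        ),
        gene_table=pd.DataFrame({"gene_id": [f"g{i:04d}" for i in range(40)]}),
        normalized=sp.csr_matrix(norm),
    )
    s = em.gene_pattern_score(ds, graph, k=8, seed=seed)
    rand = em.diffuse_random(sp.csr_matrix(norm), k=8, seed=seed).toarray()
    oracle_s = _cols_cos(norm, dense_local) - _cols_cos(norm, rand)
    out["gene_pattern_error"] = float(np.abs(s - oracle_s).max())

    d_fast = em.cross_condition_score(ds, emb, k=6)
    cond = ds.cell_table["condition"].to_numpy()
    u = np.zeros_like(norm)
    v = np.zeros_like(norm)
    for i in range(200):
        dists = np.linalg.norm(emb - emb[i], axis=1)
        same = sorted(
            (j for j in range(200) if cond[j] == cond[i] and j != i),
            key=lambda j: (dists[j], j),
        )[:6]
        other = sorted(
            (j for j in range(200) if cond[j] != cond[i]),
            key=lambda j: (dists[j], j),
        )[:6]
        u[i] = norm[same].mean(axis=0)
        v[i] = norm[other].mean(axis=0)
    oracle_d = 1.0 - _cols_cos(u, v)
    out["cross_condition_error"] = float(np.abs(d_fast - oracle_d).max())

    # layer assignment vs exhaustive scan
    exc = rng.random((1000, 2))
    layers = rng.choice(["L2/3", "L4", "L5", "L6"], size=1000)
    inn = rng.random((150, 2))
    assigned = spt.assign_layers(inn, exc, layers, k=5)
    mismatches = 0
    for i in range(150):
        d = np.linalg.norm(exc - inn[i], axis=1)
        order = np.argsort(d, kind="stable")[:5]
        nb = layers[order]
        vals, counts = np.unique(nb, return_counts=True)
        tied = set(vals[counts == counts.max()])
        mismatches += int(assigned.iloc[i].assigned_layer != next(l for l in nb if l in tied))
    out["assign_layers_mismatches"] = mismatches
    return out


def qc_toy() -> ExpressionDataset:
    """Six cells with hand-set QC metrics; gene 0 is mitochondrial.

    c0 fails the count ceiling (20000 counts), c1 the detected-gene floor
    (150 genes), c2 the mitochondrial fraction (0.10); c3-c5 pass with 5000
    counts, 300 genes and 1% mitochondrial counts.
    """
    import scipy.sparse as sp

    n_genes = 400
    counts = np.zeros((6, n_genes), dtype=int)
    specs = [
        (20000, 300, 0.01),
        (5000, 150, 0.01),
        (5000, 300, 0.10),
        (5000, 300, 0.01),
        (5000, 300, 0.01),
        (5000, 300, 0.01),
    ]
    for i, (total, n_det, mfrac) in enumerate(specs):
        mito = int(round(total * mfrac))
        rest = total - mito
        per = rest // (n_det - 1)
        counts[i, 0] = mito
        counts[i, 1:n_det] = per
        counts[i, 1] += rest - per * (n_det - 1)
    return ExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_table=pd.DataFrame({"cell_id": [f"c{i}" for i in range(6)]}),
        gene_table=pd.DataFrame(
            {"gene_id": ["mt-g0"] + [f"g{i:04d}" for i in range(1, n_genes)]}
        ),
    )


def qc_toy_survivors() -> list:
    """Cell ids surviving the default thresholds on the toy (hand: c3-c5)."""
    filtered, _ = pp.qc_filter(qc_toy())
    return sorted(filtered.cell_ids.tolist())
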