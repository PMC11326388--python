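import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from sskit import emergene as em
from sskit import preprocess as pp
from sskit import simulate as sim
from sskit.dataset import NeighborGraph, RunConfig, ValidationError
from sskit.markers import GeneSignature

from conftest import make_dataset


def graph_from_indices(indices):
    indices = np.asarray(indices)
    return NeighborGraph(
        k=indices.shape[1], indices=indices, distances=np.ones(indices.shape)
    )


class TestDiffuseLocal:
    def test_constant_gene_unchanged(self):
        x = np.full((4, 1), 3.0)
        g = graph_from_indices([[1], [0], [3], [2]])
        out = em.diffuse_local(x, g).toarray()
        np.testing.assert_allclose(out, x)

    def test_hand_example_pairs(self):
        # pairs (0,1) and (2,3); x = (1,0,0,1) -> neighbour means (0,1,1,0)
        x = np.array([[1.0], [0.0], [0.0], [1.0]])
        g = graph_from_indices([[1], [0], [3], [2]])
        out = em.diffuse_local(x, g).toarray().ravel()
        np.testing.assert_allclose(out, [0, 1, 1, 0])

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.random((200, 50))
        emb = rng.normal(size=(200, 3))
        g = pp.knn_graph(emb, k=6)
        out = em.diffuse_local(sp.csr_matrix(x), g).toarray()
        oracle = np.stack([x[g.indices[i]].mean(axis=0) for i in range(200)])
        np.testing.assert_allclose(out, oracle, atol=1e-10)

    def test_mismatched_graph_rejected(self):
        g = graph_from_indices([[1], [0]])
        with pytest.raises(ValidationError):
            em.diffuse_local(np.ones((3, 2)), g)


class TestDiffuseRandom:
    def test_constant_gene_unchanged(self):
        x = np.full((10, 1), 2.0)
        out = em.diffuse_random(x, k=3, seed=0).toarray()
        np.testing.assert_allclose(out, x)

    def test_expectation_is_leave_self_out_mean(self):
        # E[diffused value at cell i] = mean over the other cells
        rng_x = np.random.default_rng(1)
        x = rng_x.random((50, 1))
        acc = np.zeros(50)
        n_rep = 500
        for s in range(n_rep):
            acc += em.diffuse_random(x, k=5, seed=s).toarray().ravel()
        acc /= n_rep
        loo = (x.sum() - x.ravel()) / 49
        se = x.std() / np.sqrt(5 * n_rep)
        assert np.all(np.abs(acc - loo) < 4 * se)

    def test_same_seed_identical(self):
        x = np.random.default_rng(2).random((30, 4))
        a = em.diffuse_random(x, k=4, seed=11).toarray()
        b = em.diffuse_random(x, k=4, seed=11).toarray()
        np.testing.assert_array_equal(a, b)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            em.diffuse_random(np.ones((5, 1)), k=0, seed=0)
        with pytest.raises(ValidationError):
            em.diffuse_random(np.ones((5, 1)), k=5, seed=0)


class TestGenePatternScore:
    def test_constant_gene_scores_zero(self):
        norm = np.column_stack([np.full(30, 2.0), np.random.default_rng(0).random(30)])
        ds = make_dataset(np.ones((30, 2), int), normalized=norm)
        g = pp.knn_graph(np.random.default_rng(1).normal(size=(30, 2)), k=5)
        s = em.gene_pattern_score(ds, g, seed=0)
        assert s[0] == pytest.approx(0.0, abs=1e-12)

    def test_clique_gene_scores_high(self):
        # gene expressed only inside one tight spatial clique
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(400, 2)) * 10
        emb[:20] = rng.normal(size=(20, 2)) * 0.01  # tight clique
        norm = np.zeros((400, 1))
        norm[:20, 0] = 5.0
        ds = make_dataset(np.ones((400, 1), int), normalized=norm)
        g = pp.knn_graph(emb, k=10)
        s = em.gene_pattern_score(ds, g, seed=0)
        assert s[0] > 0.3

    def test_permuted_gene_scores_near_zero(self):
        # expression shuffled over cells carries no local pattern; the null
        # spread of the score for this sparse gene (50/500 cells, k=10) was
        # measured by permutation simulation: |s| has p95 ~ 0.08
        rng0 = np.random.default_rng(4)
        emb = rng0.normal(size=(500, 3))
        g = pp.knn_graph(emb, k=10)
        base = np.r_[np.full(50, 4.0), np.zeros(450)]
        scores = []
        for s in range(30):
            norm = np.random.default_rng(100 + s).permutation(base)[:, None]
            ds = make_dataset(np.ones((500, 1), int), normalized=norm)
            scores.append(em.gene_pattern_score(ds, g, seed=s)[0])
        scores = np.abs(scores)
        assert np.mean(scores < 0.1) >= 0.9
        assert np.median(scores) < 0.05

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        norm = rng.random((150, 30))
        emb = rng.normal(size=(150, 4))
        ds = make_dataset(np.ones((150, 30), int), normalized=norm)
        g = pp.knn_graph(emb, k=8)
        s = em.gene_pattern_score(ds, g, k=8, seed=7)
        local = np.stack([norm[g.indices[i]].mean(axis=0) for i in range(150)])
        rnd = em.diffuse_random(sp.csr_matrix(norm), k=8, seed=7).toarray()

        def cols_cos(a, b):
            num = (a * b).sum(axis=0)
            return num / (np.linalg.norm(a, axis=0) * np.linalg.norm(b, axis=0))

        oracle = cols_cos(norm, local) - cols_cos(norm, rnd)
        np.testing.assert_allclose(s, oracle, atol=1e-10)


class TestCrossConditionScore:
    @staticmethod
    def dataset_with_conditions(n=120, n_genes=15, seed=0):
        rng = np.random.default_rng(seed)
        norm = rng.random((n, n_genes))
        ds = make_dataset(
            np.ones((n, n_genes), int),
            normalized=norm,
            condition=["ctrl", "mut"] * (n // 2),
        )
        emb = rng.normal(size=(n, 3))
        return ds, emb, norm

    def test_matches_dense_oracle(self):
        ds, emb, norm = self.dataset_with_conditions()
        k = 5
        d = em.cross_condition_score(ds, emb, k=k)
        cond = ds.cell_table["condition"].to_numpy()
        u = np.zeros_like(norm)
        v = np.zeros_like(norm)
        for i in range(len(norm)):
            same = [j for j in range(len(norm)) if cond[j] == cond[i] and j != i]
            other = [j for j in range(len(norm)) if cond[j] != cond[i]]
            same.sort(key=lambda j: (np.linalg.norm(emb[j] - emb[i]), j))
            other.sort(key=lambda j: (np.linalg.norm(emb[j] - emb[i]), j))
            u[i] = norm[same[:k]].mean(axis=0)
            v[i] = norm[other[:k]].mean(axis=0)
        num = (u * v).sum(axis=0)
        oracle = 1 - num / (np.linalg.norm(u, axis=0) * np.linalg.norm(v, axis=0))
        np.testing.assert_allclose(d, oracle, atol=1e-10)

    def test_identical_relabelled_groups_score_zero(self):
        # co-located triplets per condition with identical expression: every
        # cell's within and cross neighbourhoods carry the same expression
        # values, so the deviation is exactly 0
        rng = np.random.default_rng(6)
        n_pos = 10
        pos_expr = rng.random((n_pos, 8))
        norm, emb, cond = [], [], []
        for j in range(n_pos):
            for c in ("ctrl", "mut"):
                for _ in range(3):
                    norm.append(pos_expr[j])
                    emb.append([100.0 * j])
                    cond.append(c)
        ds = make_dataset(
            np.ones((6 * n_pos, 8), int), normalized=np.array(norm), condition=cond
        )
        d = em.cross_condition_score(ds, np.array(emb), k=2)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_scores_lie_in_unit_interval(self):
        ds, emb, _ = self.dataset_with_conditions(seed=9)
        d = em.cross_condition_score(ds, emb, k=4)
        assert np.all((d >= 0) & (d <= 1))

    def test_small_condition_rejected(self):
        ds, emb, _ = self.dataset_with_conditions(n=12)
        with pytest.raises(ValidationError, match="needs at least"):
            em.cross_condition_score(ds, emb, k=10)


class TestBuildSignature:
    gene_ids = [f"g{i}" for i in range(6)]

    def test_disjoint_tops_concatenate(self):
        within = np.array([5.0, 4.0, 0, 0, 0, 0])
        cross = np.array([0, 0, 0, 0, 4.0, 5.0])
        sig = em.build_signature(within, cross, self.gene_ids, 2, 2)
        assert set(sig.genes) == {"g0", "g1", "g4", "g5"}
        assert set(sig.provenance) == {"specific", "differential"}

    def test_overlapping_tops_marked_both(self):
        within = np.array([5.0, 4.0, 0, 0, 0, 0])
        cross = np.array([5.0, 0, 0, 0, 0, 4.0])
        sig = em.build_signature(within, cross, self.gene_ids, 2, 2)
        prov = dict(zip(sig.genes, sig.provenance))
        assert prov["g0"] == "both"

    def test_ordered_by_best_rank(self):
        within = np.array([1.0, 3.0, 2.0, 0, 0, 0])
        cross = np.array([0, 0, 0, 0, 9.0, 1.0])
        sig = em.build_signature(within, cross, self.gene_ids, 2, 1)
        assert sig.genes[0] in {"g1", "g4"}  # both hold rank 0


class TestPermutationScoring:
    def test_minimum_attainable_p(self, null_dataset):
        sig = GeneSignature(name="s", genes=[f"g{i:04d}" for i in range(20)])
        res = em.score_cells_permutation(null_dataset, sig, n_control_sets=50, seed=0)
        n_pool = null_dataset.n_cells * 50
        assert res.p_cell.min() >= 1.0 / (1.0 + n_pool)
        assert np.all((res.p_cell > 0) & (res.p_cell <= 1))

    def test_same_seed_identical(self, null_dataset):
        sig = GeneSignature(name="s", genes=[f"g{i:04d}" for i in range(10)])
        a = em.score_cells_permutation(null_dataset, sig, n_control_sets=30, seed=4)
        b = em.score_cells_permutation(null_dataset, sig, n_control_sets=30, seed=4)
        np.testing.assert_array_equal(a.p_cell, b.p_cell)

    def test_null_p_values_near_uniform(self, null_dataset):
        # random signature on exchangeable data: rejection close to alpha
        rng = np.random.default_rng(8)
        genes = [f"g{i:04d}" for i in rng.choice(400, 50, replace=False)]
        sig = GeneSignature(name="s", genes=genes)
        res = em.score_cells_permutation(null_dataset, sig, n_control_sets=200, seed=1)
        assert 0.01 < (res.p_cell < 0.05).mean() < 0.10

    def test_empty_signature_rejected(self, null_dataset):
        with pytest.raises(ValidationError):
            em.score_cells_permutation(
                null_dataset, GeneSignature(name="s", genes=[]), seed=0
            )


class TestClusterSignificance:
    def test_all_significant_cluster(self):
        rec = em.cluster_significance(np.full(20, 0.01), ["a"] * 20)
        row = rec.iloc[0]
        assert row.frac_significant == 1.0
        assert row.gliding_p == pytest.approx(0.01)
        assert row.flagged and row.analyzed

    def test_small_cluster_not_analyzed(self):
        rec = em.cluster_significance(
            np.r_[np.full(9, 0.01), np.full(15, 0.5)], ["tiny"] * 9 + ["big"] * 15
        )
        by = rec.set_index("cluster")
        assert not by.loc["tiny", "analyzed"]
        assert by.loc["big", "analyzed"]

    def test_forty_percent_not_flagged(self):
        p = np.r_[np.full(8, 0.01), np.full(12, 0.5)]
        rec = em.cluster_significance(p, ["c"] * 20)
        assert not rec.iloc[0].flagged
        assert rec.iloc[0].frac_significant == pytest.approx(0.4)

    def test_gliding_percentile_interpolates(self):
        p = np.array([0.1, 0.2, 0.3, 0.4])
        rec = em.cluster_significance(p, ["c"] * 4, percentile=50)
        assert rec.iloc[0].gliding_p == pytest.approx(0.25)


class TestPipeline:
    def test_signature_recovers_planted_program(self):
        # fezf2like-style design: the differential program must enter the
        # combinatorial signature with high recall
        spec = sim.fezf2like_reference_spec(n_cells=2000, n_genes=1500, seed=0)
        prog = sim.default_program_genes(spec, 50)
        effects = [sim.ConditionEffect("program_shift", "SST",
                                       program_genes=prog, program_fold=4.0)]
        cfg = RunConfig(seed=0, n_control_sets=200)
        data = sim.simulate_conditions(spec, effects, seed=cfg.child_seed("sim"))
        data = pp.normalize_log(data)
        hvgs = pp.select_hvgs_pearson(data, n_top=data.n_genes)
        emb = pp.embed_svd(data, hvgs, n_comps=50)
        graph = pp.knn_graph(emb, k=15)
        res = em.run_emergene(
            data, emb, graph,
            clusters=data.cell_table["cell_type"].to_numpy(), config=cfg,
        )
        planted = {f"g{i:04d}" for i in prog}
        recall = len(planted & set(res.signature.genes)) / len(planted)
        assert recall >= 0.5
        rec = res.cluster_records.set_index("cluster")
        assert rec.loc["SST|mut", "frac_significant"] > rec.drop(
            index="SST|mut"
        )["frac_significant"].max()
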