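import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from sskit import preprocess as pp
from sskit import simulate as sim
from sskit.dataset import ValidationError

from conftest import make_dataset


from sskit.benchmarks import qc_toy  # six-cell toy with hand-set QC metrics


class TestQC:
    def test_toy_retains_hand_derived_cells(self):
        filtered, report = pp.qc_filter(qc_toy())
        assert set(filtered.cell_ids) == {"c3", "c4", "c5"}
        assert report["n_cells_retained"] == 3

    def test_all_passing_is_identity_on_cells(self):
        ds = qc_toy().subset_cells(np.array([3, 4, 5]))
        filtered, _ = pp.qc_filter(ds)
        assert filtered.cell_ids.tolist() == ds.cell_ids.tolist()

    def test_gene_in_two_retained_cells_dropped(self):
        ds = qc_toy()
        # gene 399 expressed only in two passing cells
        counts = ds.counts.toarray()
        counts[3, 399] = counts[4, 399] = 1
        ds = make_dataset(counts, gene_ids=ds.gene_table["gene_id"].tolist())
        filtered, _ = pp.qc_filter(ds)
        assert "g0399" not in set(filtered.gene_ids)

    def test_doublet_column_honored(self):
        ds = qc_toy()
        ds.cell_table["doublet_score"] = [0.0, 0.0, 0.0, 0.5, 0.0, 0.0]
        filtered, _ = pp.qc_filter(ds, pp.QCThresholds(min_cells_per_gene=2))
        assert set(filtered.cell_ids) == {"c4", "c5"}

    def test_order_independence_of_criteria(self):
        # criteria are conjunctive on precomputed metrics: the retained set
        # equals the intersection of single-criterion survivors
        ds = qc_toy()
        filtered, report = pp.qc_filter(ds)
        m = pp.qc_metrics(ds)
        th = pp.QCThresholds()
        masks = [
            m["n_counts"] < th.max_counts,
            m["n_genes"] > th.min_genes,
            m["n_genes"] < th.max_genes,
            m["frac_mito"] < th.max_mito,
            m["frac_ribo"] < th.max_ribo,
        ]
        for perm in itertools.permutations(range(5)):
            keep = np.ones(6, dtype=bool)
            for i in perm:
                keep &= masks[i].to_numpy()
            assert set(ds.cell_ids[keep]) == set(filtered.cell_ids)

    def test_empty_result_errors_with_report(self):
        ds = qc_toy().subset_cells(np.array([0]))
        with pytest.raises(ValidationError, match="report"):
            pp.qc_filter(ds)

    def test_threshold_validation(self):
        with pytest.raises(ValidationError):
            pp.QCThresholds(min_genes=500, max_genes=400)


class TestNormalize:
    def test_hand_arithmetic(self):
        ds = make_dataset(np.array([[2, 2, 6]]))
        out = pp.normalize_log(ds, target_sum=10)
        expected = np.log1p(np.array([2.0, 2.0, 6.0]))
        np.testing.assert_allclose(out.normalized.toarray().ravel(), expected)

    def test_prelog_row_sums_hit_target(self, typed_dataset):
        pre = np.expm1(typed_dataset.normalized.toarray())
        np.testing.assert_allclose(pre.sum(axis=1), 10000.0, rtol=1e-9)

    def test_zeros_stay_zero_and_counts_untouched(self):
        ds = make_dataset(np.array([[0, 5], [3, 0]]))
        out = pp.normalize_log(ds)
        assert out.normalized[0, 0] == 0
        assert (out.counts != ds.counts).nnz == 0

    def test_relative_proportions_recoverable(self):
        ds = make_dataset(np.array([[1, 3, 6], [2, 2, 2]]))
        out = pp.normalize_log(ds, target_sum=100)
        pre = np.expm1(out.normalized.toarray())
        props = pre / pre.sum(axis=1, keepdims=True)
        raw = ds.counts.toarray()
        np.testing.assert_allclose(props, raw / raw.sum(axis=1, keepdims=True), rtol=1e-12)

    def test_zero_count_cell_rejected(self):
        with pytest.raises(ValidationError):
            pp.normalize_log(make_dataset(np.array([[0, 0], [1, 1]])))


class TestHVG:
    def test_null_gene_ranks_last(self):
        # a gene exactly proportional to cell totals has residual ~ 0
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(100, 20))
        counts[:, 0] = counts[:, 1:].sum(axis=1) // 5  # tracks totals
        ds = make_dataset(counts)
        ranked = pp.select_hvgs_pearson(ds, n_top=20)
        assert ranked[-1] == "g0000"

    def test_planted_marker_ranks_top(self, typed_dataset):
        ranked = pp.select_hvgs_pearson(typed_dataset, n_top=typed_dataset.n_genes)
        top_pct = set(ranked[: max(3, typed_dataset.n_genes // 100)])
        planted = {f"g{i:04d}" for i in range(30)}
        assert top_pct <= planted

    def test_default_n_top(self):
        import inspect

        assert inspect.signature(pp.select_hvgs_pearson).parameters["n_top"].default == 5000

    def test_all_zero_gene_rejected(self):
        with pytest.raises(ValidationError):
            pp.select_hvgs_pearson(make_dataset(np.array([[1, 0], [2, 0]])))

    def test_agrees_with_scanpy_residual_ranking(self, typed_dataset):
        sc = pytest.importorskip("scanpy")
        import anndata as ad

        adata = ad.AnnData(X=typed_dataset.counts.copy())
        adata.var_names = typed_dataset.gene_ids
        sc.experimental.pp.highly_variable_genes(
            adata, flavor="pearson_residuals", n_top_genes=50, theta=100
        )
        ours = set(pp.select_hvgs_pearson(typed_dataset, n_top=50))
        theirs = set(adata.var_names[adata.var["highly_variable"]])
        assert len(ours & theirs) >= 45


class TestEmbed:
    def test_single_axis_of_variation_dominates(self):
        # two repeated cell profiles: the residual matrix has one dominant
        # direction, so component 1 carries almost all the variance
        counts = np.ones((40, 10), dtype=int)
        counts[:20, :5] = 10
        counts[20:, 5:] = 10
        ds = make_dataset(counts)
        emb = pp.embed_svd(ds, [f"g{i:04d}" for i in range(10)], n_comps=3)
        var = emb.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_reproducible_and_orthogonal(self, typed_dataset):
        hvgs = pp.select_hvgs_pearson(typed_dataset, n_top=100)
        a = pp.embed_svd(typed_dataset, hvgs, n_comps=10)
        b = pp.embed_svd(typed_dataset, hvgs, n_comps=10)
        np.testing.assert_array_equal(a, b)
        gram = a.T @ a
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() / np.abs(np.diag(gram)).max() < 1e-8

    def test_too_many_components_rejected(self, typed_dataset):
        with pytest.raises(ValidationError):
            pp.embed_svd(typed_dataset, ["g0000", "g0001"], n_comps=5)


class TestKNN:
    def test_collinear_points(self):
        g = pp.knn_graph(np.array([[0.0], [1.0], [3.0]]), k=1)
        assert g.indices.ravel().tolist() == [1, 0, 1]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(200, 5))
        g = pp.knn_graph(x, k=7)
        for i in range(200):
            d = np.linalg.norm(x - x[i], axis=1)
            order = sorted(range(200), key=lambda j: (d[j], j))
            order = [j for j in order if j != i][:7]
            assert g.indices[i].tolist() == order
            np.testing.assert_allclose(g.distances[i], d[order], atol=1e-10)

    def test_duplicate_coordinates_tie_break_by_index(self):
        x = np.zeros((4, 2))
        g = pp.knn_graph(x, k=2)
        assert g.indices[0].tolist() == [1, 2]
        assert g.indices[3].tolist() == [0, 1]

    def test_invalid_k_rejected(self):
        with pytest.raises(ValidationError):
            pp.knn_graph(np.zeros((5, 2)), k=0)
        with pytest.raises(ValidationError):
            pp.knn_graph(np.zeros((5, 2)), k=5)


class TestLeiden:
    @staticmethod
    def blob_embedding(seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(150, 4))
        b = rng.normal(12, 1, size=(150, 4))
        return np.vstack([a, b]), np.array([0] * 150 + [1] * 150)

    def test_two_blobs_recovered(self):
        emb, truth = self.blob_embedding()
        labels = pp.cluster_leiden(pp.knn_graph(emb, k=10), resolution=0.1, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.95

    def test_identical_cells_single_cluster(self):
        labels = pp.cluster_leiden(pp.knn_graph(np.zeros((30, 2)), k=5), seed=0)
        assert len(np.unique(labels)) == 1

    def test_same_seed_identical_labels(self):
        emb, _ = self.blob_embedding(seed=3)
        g = pp.knn_graph(emb, k=10)
        np.testing.assert_array_equal(
            pp.cluster_leiden(g, seed=7), pp.cluster_leiden(g, seed=7)
        )


class TestLeidenLocal:
    @staticmethod
    def nested_dataset():
        # cluster 0: two planted subtypes; cluster 1: homogeneous
        types = [
            sim.CellTypeSpec("A1", 0.3, marker_genes=range(0, 8), marker_fold=10.0),
            sim.CellTypeSpec("A2", 0.3, marker_genes=range(8, 16), marker_fold=10.0),
            sim.CellTypeSpec("B", 0.4, marker_genes=range(16, 24), marker_fold=10.0),
        ]
        spec = sim.PopulationSpec(types, n_cells=600, n_genes=200, seed=21)
        data = pp.normalize_log(sim.simulate_reference(spec))
        coarse = np.where(data.cell_table["cell_type"] == "B", 1, 0)
        return data, coarse

    def test_unselected_labels_bit_identical(self):
        data, coarse = self.nested_dataset()
        refined = pp.leiden_local(data, coarse, [0], n_hvgs=100, n_comps=20, k=10, seed=0)
        outside = coarse == 1
        assert all(refined[outside][i] == 1 for i in range(outside.sum()))

    def test_planted_subtypes_split(self):
        data, coarse = self.nested_dataset()
        refined = pp.leiden_local(data, coarse, [0], n_hvgs=100, n_comps=20, k=10, seed=0)
        inside = coarse == 0
        sub_truth = data.cell_table.loc[inside, "cell_type"].to_numpy()
        assert adjusted_rand_score(sub_truth, refined[inside].astype(str)) > 0.9
        assert all(str(l).startswith("0.") for l in refined[inside])

    def test_selection_smaller_than_k_rejected(self):
        data, coarse = self.nested_dataset()
        tiny = coarse.copy()
        tiny[:] = 1
        tiny[:5] = 0
        with pytest.raises(ValidationError, match="too small"):
            pp.leiden_local(data, tiny, [0], k=10)

    def test_unknown_cluster_rejected(self):
        data, coarse = self.nested_dataset()
        with pytest.raises(ValidationError):
            pp.leiden_local(data, coarse, [99], k=5)
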