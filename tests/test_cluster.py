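"""HVG selection, regression/scaling, PCA, kNN, Louvain, UMAP."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from heartregen import cluster, qc, sim
from conftest import lognorm_from_dense, make_count_matrix


def hvg_oracle(lognorm_dense, cfg):
    """Independently coded binning oracle for HVG selection."""
    X = np.expm1(lognorm_dense)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    lm = np.log1p(mean)
    edges = np.linspace(lm.min(), lm.max(), cfg.n_bins + 1)
    which = np.clip(np.digitize(lm, edges[1:-1]), 0, cfg.n_bins - 1)
    z = np.zeros_like(disp)
    for b in set(which):
        sel = which == b
        if sel.sum() < 2:
            continue
        sd = disp[sel].std(ddof=1)
        if sd > 0:
            z[sel] = (disp[sel] - disp[sel].mean()) / sd
    return (lm > cfg.min_mean) & (lm < cfg.max_mean) & (z >= cfg.min_disp)


class TestSelectHvgs:
    def test_constant_nonzero_gene_never_hvg(self):
        rng = np.random.default_rng(0)
        dense = np.log1p(rng.poisson(2.0, size=(40, 30)).astype(float))
        dense[:, 3] = np.log1p(2.0)  # zero variance
        out = cluster.select_hvgs(lognorm_from_dense(dense))
        assert not out.loc[3, "highly_variable"]

    def test_high_abundance_gene_excluded_by_max_mean(self):
        rng = np.random.default_rng(1)
        dense = np.log1p(rng.poisson(2.0, size=(40, 30)).astype(float))
        dense[:, 7] = np.log1p(rng.poisson(200.0, size=40).astype(float))
        out = cluster.select_hvgs(lognorm_from_dense(dense))
        assert out.loc[7, "log1p_mean"] > 4.0
        assert not out.loc[7, "highly_variable"]

    def test_matches_independent_binning_oracle(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(rng.uniform(0.2, 6.0, size=50), size=(80, 50))
        dense = np.log1p(base.astype(float))
        cfg = cluster.HVGConfig()
        out = cluster.select_hvgs(lognorm_from_dense(dense), cfg)
        np.testing.assert_array_equal(
            out["highly_variable"].to_numpy(), hvg_oracle(dense, cfg)
        )

    def test_raising_min_disp_never_adds_hvgs(self):
        rng = np.random.default_rng(3)
        dense = np.log1p(rng.poisson(2.0, size=(60, 40)).astype(float))
        ln = lognorm_from_dense(dense)
        loose = cluster.select_hvgs(ln, cluster.HVGConfig(min_disp=0.25))
        strict = cluster.select_hvgs(ln, cluster.HVGConfig(min_disp=0.75))
        assert set(np.flatnonzero(strict["highly_variable"])) <= set(
            np.flatnonzero(loose["highly_variable"])
        )

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            cluster.select_hvgs(lognorm_from_dense(np.zeros((5, 5))))


class TestRegressAndScale:
    def test_equal_covariates_reduce_to_centered_scaling(self):
        rng = np.random.default_rng(4)
        dense = rng.normal(size=(30, 8))
        covs = np.ones((30, 2)) * 3.0
        out = cluster.regress_and_scale(dense, covs)
        centered = dense - dense.mean(axis=0)
        expected = centered / centered.std(axis=0, ddof=1)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_planted_covariate_effect_removed(self):
        rng = np.random.default_rng(5)
        cov = rng.normal(size=(50, 1))
        dense = rng.normal(size=(50, 6)) + cov * rng.normal(size=6)
        out = cluster.regress_and_scale(dense, cov)
        for j in range(6):
            r = np.corrcoef(out[:, j], cov.ravel())[0, 1]
            assert abs(r) < 1e-8

    def test_output_means_zero(self):
        rng = np.random.default_rng(6)
        out = cluster.regress_and_scale(
            rng.normal(size=(40, 10)), rng.normal(size=(40, 2))
        )
        assert np.abs(out.mean(axis=0)).max() < 1e-10

    def test_covariate_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cluster.regress_and_scale(np.zeros((10, 3)), np.zeros((9, 2)))


class TestComputePca:
    def test_explained_variances_non_increasing(self):
        rng = np.random.default_rng(7)
        _, _, ev = cluster.compute_pca(rng.normal(size=(50, 20)), n_pcs=10)
        assert (np.diff(ev) <= 1e-12).all()

    def test_rank_two_fixture_has_two_nonzero_variances(self):
        rng = np.random.default_rng(8)
        basis = rng.normal(size=(2, 10))
        data = rng.normal(size=(30, 2)) @ basis
        _, _, ev = cluster.compute_pca(data - data.mean(0), n_pcs=5)
        assert (ev[:2] > 1e-8).all() and (ev[2:] < 1e-10).all()

    def test_scores_match_svd_oracle_up_to_sign(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(20, 10))
        centered = data - data.mean(axis=0)
        scores, comps, _ = cluster.compute_pca(data, n_pcs=4)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        oracle = u[:, :4] * s[:4]
        for j in range(4):
            assert np.allclose(scores[:, j], oracle[:, j], atol=1e-8) or np.allclose(
                scores[:, j], -oracle[:, j], atol=1e-8
            )
            # documented sign convention: largest-magnitude loading positive
            assert comps[j, np.argmax(np.abs(comps[j]))] > 0

    def test_n_pcs_too_large_rejected(self):
        with pytest.raises(ValueError):
            cluster.compute_pca(np.zeros((5, 3)), n_pcs=4)


class TestKnnGraph:
    def test_two_points_mutual_edge(self):
        g = cluster.knn_graph(np.array([[0.0], [1.0]]), k=1)
        assert g.adjacency[0, 1] == 1 and g.adjacency[1, 0] == 1

    def test_neighbors_match_brute_force(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(100, 5))
        g = cluster.knn_graph(pts, k=10)
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for i in range(100):
            brute = set(np.argsort(d2[i], kind="stable")[:10])
            assert set(g.indices[i]) == brute

    def test_no_self_loops_and_symmetric(self):
        rng = np.random.default_rng(11)
        g = cluster.knn_graph(rng.normal(size=(30, 3)), k=5)
        assert g.adjacency.diagonal().sum() == 0
        assert (g.adjacency != g.adjacency.T).nnz == 0

    def test_k_not_less_than_n_rejected(self):
        with pytest.raises(ValueError):
            cluster.knn_graph(np.zeros((5, 2)), k=5)


class TestLouvain:
    def test_two_disconnected_cliques_two_clusters(self):
        blocks = sp.block_diag(
            [np.ones((10, 10)) - np.eye(10), np.ones((10, 10)) - np.eye(10)]
        )
        labels = cluster.louvain_cluster(sp.csr_matrix(blocks), resolution=1.0, seed=0)
        assert len(set(labels)) == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1

    def test_labels_size_ordered_and_deterministic(self):
        blocks = sp.block_diag(
            [np.ones((5, 5)) - np.eye(5), np.ones((12, 12)) - np.eye(12)]
        )
        l1 = cluster.louvain_cluster(sp.csr_matrix(blocks), seed=3)
        l2 = cluster.louvain_cluster(sp.csr_matrix(blocks), seed=3)
        np.testing.assert_array_equal(l1, l2)
        assert l1[10] == 0  # the larger clique gets label 0
        assert l1[0] == 1

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            cluster.louvain_cluster(sp.csr_matrix((0, 0)), seed=0)


class TestEndToEnd:
    def test_planted_four_types_recovered(self):
        cfg = sim.planted_types_config(n_types=4, cells_per_type=150, n_genes=600, seed=5)
        matrix, truth = sim.simulate_sample(cfg, "sample1")
        res = cluster.run_cluster_pipeline(
            matrix, cluster.ClusterConfig(seed=5), with_umap=False
        )
        ari = adjusted_rand_score(truth["cell_type"].to_numpy(), res.labels)
        assert ari >= 0.9

    def test_subset_of_single_type_one_dominant_cluster(self):
        cfg = sim.planted_types_config(n_types=3, cells_per_type=120, n_genes=500, seed=6)
        matrix, truth = sim.simulate_sample(cfg, "sample1")
        mask = (truth["cell_type"] == "type1").to_numpy()
        res = cluster.subset_and_recluster(
            matrix, mask, cluster.ClusterConfig(louvain_resolution=0.5, seed=6),
            with_umap=False,
        )
        counts = np.bincount(res.labels)
        assert counts.max() / counts.sum() > 0.9

    def test_subset_too_small_rejected(self):
        cfg = sim.planted_types_config(n_types=2, cells_per_type=60, n_genes=400, seed=7)
        matrix, _ = sim.simulate_sample(cfg, "sample1")
        mask = np.zeros(matrix.n_cells, dtype=bool)
        mask[:5] = True
        with pytest.raises(ValueError, match="too small"):
            cluster.subset_and_recluster(matrix, mask)

    def test_cluster_sample_table_sums_to_n_cells(self, small_dataset):
        _, matrix, _ = small_dataset
        kept, _ = qc.filter_low_gene_cells(matrix, 100)
        res = cluster.run_cluster_pipeline(
            kept, cluster.ClusterConfig(seed=0), with_umap=False
        )
        assert res.counts.to_numpy().sum() == kept.n_cells
        assert res.labels.min() == 0
        assert set(np.unique(res.labels)) == set(range(res.n_clusters))


class TestUmap:
    def test_shape_determinism_and_trustworthiness(self):
        from sklearn.manifold import trustworthiness

        cfg = sim.planted_types_config(n_types=3, cells_per_type=60, n_genes=400, seed=8)
        matrix, _ = sim.simulate_sample(cfg, "sample1")
        res = cluster.run_cluster_pipeline(matrix, cluster.ClusterConfig(seed=8))
        n = matrix.n_cells
        assert res.embedding.shape == (n, 2)
        assert np.isfinite(res.embedding).all()
        res2 = cluster.run_cluster_pipeline(matrix, cluster.ClusterConfig(seed=8))
        np.testing.assert_array_equal(res.embedding, res2.embedding)
        t = trustworthiness(res.pca_scores, res.embedding, n_neighbors=15)
        assert t > 0.8
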