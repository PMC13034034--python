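"""QC filtering, normalization, HVG selection and PCA."""

import warnings

import numpy as np
import pytest
import scipy.sparse as sp

import trichoflow as tf


def make_matrix(counts, samples=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    return tf.CountMatrix(
        counts=counts,
        barcodes=[f"B{i:03d}" for i in range(n)],
        genes=[f"g{j:03d}" for j in range(g)],
        sample_labels=samples or ["S1"] * n,
    )


class TestFilterCells:
    def test_cell_above_gene_bound_removed(self):
        rng = np.random.default_rng(0)
        # 9000 genes; one cell detects 8001 of them, another detects 1000
        counts = np.zeros((2, 9000), dtype=int)
        counts[0, :8001] = 1
        counts[1, :1000] = 1
        cm = make_matrix(counts)
        filtered, report = tf.filter_cells(cm)
        assert list(filtered.barcodes) == ["B001"]
        assert report.n_before == 2 and report.n_after == 1

    def test_all_cells_within_bounds_retained(self):
        counts = np.zeros((5, 1200), dtype=int)
        counts[:, :1000] = 5  # 1000 genes detected, 5000 UMIs
        filtered, report = tf.filter_cells(make_matrix(counts))
        assert report.retention == 1.0

    def test_umi_cap_is_strict(self):
        counts = np.zeros((2, 300), dtype=int)
        counts[0, :250] = 200  # 50 000 UMIs exactly -> excluded (< cap)
        counts[1, :250] = 199
        filtered, _ = tf.filter_cells(make_matrix(counts))
        assert list(filtered.barcodes) == ["B001"]

    def test_matches_independent_recount(self, small_sim_config):
        sim = tf.simulate_experiment(small_sim_config)
        filtered, _ = tf.filter_cells(sim.counts, 200, 8000, 50_000)
        dense = np.asarray(sim.counts.counts.todense())
        keep = [
            i for i in range(dense.shape[0])
            if 200 <= (dense[i] > 0).sum() <= 8000 and dense[i].sum() < 50_000
        ]
        assert list(filtered.barcodes) == list(sim.counts.barcodes[keep])

    def test_idempotent(self, small_sim_config):
        sim = tf.simulate_experiment(small_sim_config)
        once, _ = tf.filter_cells(sim.counts)
        twice, _ = tf.filter_cells(once)
        assert list(once.barcodes) == list(twice.barcodes)

    def test_empty_result_names_bounds(self):
        counts = np.ones((3, 10), dtype=int)  # 10 genes < min_genes
        with pytest.raises(ValueError, match="bounds"):
            tf.filter_cells(make_matrix(counts))


class TestNormalize:
    def test_zero_stays_zero_and_closed_form(self):
        counts = sp.csr_matrix(np.array([[7, 0]]))
        out = tf.normalize_log1p(counts, scale=1e4)
        assert out[0, 1] == 0.0
        # single expressed gene carries the whole library
        assert out[0, 0] == pytest.approx(np.log1p(1e4))

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3, size=(20, 15))
        counts[:, 0] += 1  # no zero-total cells
        out = np.asarray(tf.normalize_log1p(sp.csr_matrix(counts)).todense())
        totals = counts.sum(axis=1, keepdims=True)
        expected = np.log1p(1e4 * counts / totals)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_zero_total_cell_rejected(self):
        counts = sp.csr_matrix(np.array([[1, 2], [0, 0]]))
        with pytest.raises(ValueError, match="zero total"):
            tf.normalize_log1p(counts)


class TestVariableGenes:
    def test_tie_break_by_gene_id(self):
        rng = np.random.default_rng(0)
        # every gene is a permutation of the same values: variances tie
        # exactly, so the selection falls back to gene-ID order
        values = rng.poisson(5, size=50).astype(float)
        X = np.stack([rng.permutation(values) for _ in range(10)], axis=1)
        genes = np.array([f"g{j}" for j in range(10)])
        top = tf.select_variable_genes(sp.csr_matrix(X), genes, n_top=4)
        assert list(top) == ["g0", "g1", "g2", "g3"]

    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(3.0, size=(60, 6)).astype(float)
        X[:, 2] = 1.0  # constant gene
        genes = np.array([f"g{j}" for j in range(6)])
        top = tf.select_variable_genes(sp.csr_matrix(X), genes, n_top=5)
        assert "g2" not in top

    def test_markers_rank_among_most_variable(self, small_sim_config):
        sim = tf.simulate_experiment(small_sim_config)
        filtered, _ = tf.filter_cells(sim.counts)
        norm = tf.normalize_log1p(filtered.counts)
        top = set(tf.select_variable_genes(norm, filtered.genes, n_top=400))
        markers = [g for genes in sim.truth.markers_by_type.values()
                   for g in genes]
        assert np.mean([g in top for g in markers]) >= 0.9

    def test_n_top_exceeding_genes_warns(self):
        X = sp.csr_matrix(np.random.default_rng(0).poisson(3, (30, 5)) + 1.0)
        with pytest.warns(UserWarning, match="exceeds"):
            tf.select_variable_genes(X, np.array(list("abcde")), n_top=10)


class TestPCA:
    def test_rank_one_data_captured_by_first_component(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=100)
        direction = rng.normal(size=8)
        X = np.outer(t, direction)
        genes = np.array([f"g{j}" for j in range(8)])
        emb = tf.pca_embed(sp.csr_matrix(X), genes, genes, k=3, scale=False)
        assert emb.variance_ratio[0] >= 0.999

    def test_duplicate_rows_get_identical_coordinates(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        X = np.vstack([X, X[:5]])
        genes = np.array([f"g{j}" for j in range(6)])
        emb = tf.pca_embed(sp.csr_matrix(X), genes, genes, k=3)
        np.testing.assert_allclose(emb.coords[40:45], emb.coords[:5], atol=1e-8)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 7))
        genes = np.array([f"g{j}" for j in range(7)])
        emb = tf.pca_embed(sp.csr_matrix(X), genes, genes, k=4)
        # oracle: eigen-decomposition of the covariance of the scaled data
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        cov = Z.T @ Z / (Z.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:4]
        for j, col in enumerate(order):
            v = evecs[:, col]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(emb.loadings[j], v, atol=1e-8)
            np.testing.assert_allclose(emb.coords[:, j], Z @ v, atol=1e-7)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 6))
        genes = np.array([f"g{j}" for j in range(6)])
        emb1 = tf.pca_embed(sp.csr_matrix(X), genes, genes, k=3)
        perm = rng.permutation(6)
        emb2 = tf.pca_embed(sp.csr_matrix(X[:, perm]), genes[perm], genes, k=3)
        np.testing.assert_allclose(emb1.coords, emb2.coords, atol=1e-8)

    def test_variance_shares_bounded(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 10))
        genes = np.array([f"g{j}" for j in range(10)])
        emb = tf.pca_embed(sp.csr_matrix(X), genes, genes, k=5)
        assert emb.variance_ratio.sum() <= 1.0 + 1e-12

    def test_k_above_rank_reduced_with_warning(self):
        X = np.random.default_rng(8).normal(size=(5, 10))
        genes = np.array([f"g{j}" for j in range(10)])
        with pytest.warns(UserWarning, match="reducing"):
            emb = tf.pca_embed(sp.csr_matrix(X), genes, genes, k=9)
        assert emb.n_components == 5

    def test_depth_covariate_removed(self):
        rng = np.random.default_rng(9)
        depth = rng.normal(size=60)
        X = np.outer(depth, rng.uniform(0.5, 1.5, 8)) + 0.1 * rng.normal(size=(60, 8))
        genes = np.array([f"g{j}" for j in range(8)])
        emb = tf.pca_embed(sp.csr_matrix(X), genes, genes, k=2, covariates=depth)
        corr = abs(np.corrcoef(emb.coords[:, 0], depth)[0, 1])
        assert corr < 0.2
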