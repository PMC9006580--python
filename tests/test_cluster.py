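"""PCA, SNN-graph construction and modularity clustering."""

import numpy as np
import pytest
import scipy.sparse as sp

from degentraj.cluster import (
    PCSpace,
    SNNGraph,
    build_snn,
    graph_modularity,
    modularity_cluster,
    run_pca,
)


def brute_force_knn(X, k):
    from scipy.spatial.distance import cdist
    D = cdist(X, X)
    return np.argsort(D, axis=1, kind="stable")[:, :k]


def brute_force_modularity(W, labels, resolution):
    W = np.asarray(W.todense() if sp.issparse(W) else W, float)
    k = W.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    for i in range(len(labels)):
        for j in range(len(labels)):
            if labels[i] == labels[j]:
                q += (W[i, j] - resolution * k[i] * k[j] / two_m) / two_m
    return q


class TestPCA:
    def test_planar_data_has_two_informative_components(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 30))
        coeff = rng.normal(size=(100, 2))
        X = (coeff @ basis).T  # genes × cells, rank 2
        pcs = run_pca(X, n_components=10)
        assert pcs.explained_variance[2:].sum() < 1e-8 * pcs.explained_variance[:2].sum()

    def test_duplicated_cells_get_identical_coordinates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 40))
        X[:, 1] = X[:, 0]
        pcs = run_pca(X, n_components=5)
        np.testing.assert_allclose(pcs.coords[0], pcs.coords[1], atol=1e-10)

    def test_total_explained_variance_matches_data_variance(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 60))
        pcs = run_pca(X, n_components=30)
        total_var = np.var(X.T - X.T.mean(axis=0), axis=0, ddof=1).sum()
        assert pcs.explained_variance.sum() == pytest.approx(total_var, rel=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            run_pca(np.zeros((10, 5)), n_components=20)


class TestSNN:
    def test_identical_neighbor_sets_give_weight_one(self):
        # tight pairs far apart: each pair member's kNN set is exactly the pair
        X = np.array([[0.0, 0], [0.01, 0], [10, 10], [10.01, 10],
                      [0, 50], [0.01, 50], [100, 15], [100.01, 15]])
        g = build_snn(X, k_neighbors=2, prune_threshold=0.0)
        assert g.weights[0, 1] == pytest.approx(1.0)

    def test_no_self_loops_and_weights_in_unit_interval(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(100, 5))
        g = build_snn(X, k_neighbors=10)
        assert g.weights.diagonal().sum() == 0
        assert g.weights.data.min() > 0 and g.weights.data.max() <= 1.0

    def test_separated_blobs_have_no_cross_edges(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 1, size=(30, 3)), rng.normal(50, 1, size=(30, 3))])
        g = build_snn(X, k_neighbors=10)
        W = g.weights.tocoo()
        # oracle: brute-force kNN shows neighbor sets never cross blobs
        knn = brute_force_knn(X, 11)
        assert (knn[:30] < 30).all() and (knn[30:] >= 30).all()
        cross = ((W.row < 30) & (W.col >= 30)) | ((W.row >= 30) & (W.col < 30))
        assert not cross.any()

    def test_k_must_be_less_than_n(self):
        with pytest.raises(ValueError, match="k_neighbors"):
            build_snn(np.zeros((5, 2)), k_neighbors=5)


def two_cliques(n=10, w=1.0):
    W = np.zeros((2 * n, 2 * n))
    W[:n, :n] = w
    W[n:, n:] = w
    np.fill_diagonal(W, 0)
    return SNNGraph(sp.csr_matrix(W), k_neighbors=n, prune_threshold=0.0)


class TestModularityClustering:
    def test_disconnected_cliques_recovered_exactly(self):
        g = two_cliques()
        out = modularity_cluster(g, resolution=0.8, seed=0)
        labels = out.labels
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:10])) == 1 and len(np.unique(labels[10:])) == 1

    def test_vanishing_resolution_merges_everything(self):
        rng = np.random.default_rng(5)
        W = (rng.random((30, 30)) < 0.3).astype(float)
        W = np.triu(W, 1); W = W + W.T
        W[0, 1] = W[1, 0] = 1.0  # ensure some edge
        g = SNNGraph(sp.csr_matrix(W), 5, 0.0)
        out = modularity_cluster(g, resolution=1e-6, seed=0)
        from scipy.sparse.csgraph import connected_components
        n_comp, _ = connected_components(g.weights, directed=False)
        assert len(np.unique(out.labels)) == n_comp

    def test_reported_modularity_equals_brute_force_recomputation(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(i * 8, 1, size=(20, 4)) for i in range(3)])
        g = build_snn(X, k_neighbors=8)
        out = modularity_cluster(g, resolution=0.8, seed=0)
        q = brute_force_modularity(g.weights, out.labels, 0.8)
        assert out.modularity == pytest.approx(q, abs=1e-10)

    def test_partition_beats_trivial_partitions(self):
        g = two_cliques()
        out = modularity_cluster(g, resolution=1.0, seed=0)
        n = g.weights.shape[0]
        q_single = graph_modularity(g.weights, np.zeros(n, int), 1.0)
        q_atomic = graph_modularity(g.weights, np.arange(n), 1.0)
        assert out.modularity >= q_single and out.modularity >= q_atomic

    def test_same_partition_after_cell_permutation(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(i * 8, 1, size=(25, 4)) for i in range(3)])
        g = build_snn(X, k_neighbors=8)
        out = modularity_cluster(g, resolution=0.8, seed=3)
        perm = rng.permutation(X.shape[0])
        g2 = build_snn(X[perm], k_neighbors=8)
        out2 = modularity_cluster(g2, resolution=0.8, seed=3)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(out.labels[perm], out2.labels) == pytest.approx(1.0)

    def test_empty_graph_rejected(self):
        g = SNNGraph(sp.csr_matrix((5, 5)), 2, 0.0)
        with pytest.raises(ValueError, match="empty"):
            modularity_cluster(g)


def test_populations_recovered_with_high_ari(pipeline_run):
    """Louvain on the SNN graph recovers the planted populations/stages."""
    from sklearn.metrics import adjusted_rand_score
    res = pipeline_run
    cells = res.cells
    singlet = ~cells["doublet"].to_numpy() & ~cells["lowq"].to_numpy()
    ari = adjusted_rand_score(cells["stage"].to_numpy()[singlet], res.clusters[singlet])
    assert ari >= 0.9
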