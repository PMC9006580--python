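"""PCA embedding, shared-nearest-neighbor graph and modularity clustering.

Cells are embedded with PCA on the scaled matrix (first 50 components by
default), connected in an SNN graph whose edge weights are the Jaccard
overlap of k-nearest-neighbor sets (each cell counts as its own neighbor,
weights <= 1/15 pruned), and partitioned by Louvain modularity optimization
with a resolution parameter (0.8 by default).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors


@dataclass
class PCSpace:
    coords: np.ndarray        # cells × components
    loadings: np.ndarray      # genes × components
    explained_variance: np.ndarray


@dataclass
class SNNGraph:
    weights: sp.csr_matrix    # symmetric, zero diagonal
    k_neighbors: int
    prune_threshold: float


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    resolution: float
    modularity: float


def run_pca(scaled: np.ndarray, n_components: int = 50, seed: int = 0) -> PCSpace:
    """PCA of the scaled gene×cell matrix (cells are observations).

    Component signs are fixed so each component's largest-magnitude gene
    loading is positive.
    """
    X = np.asarray(scaled).T  # cells × genes
    max_rank = min(X.shape)
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds min(genes, cells)={max_rank}")
    pca = PCA(n_components=n_components, svd_solver="full" if max_rank <= 600 else "randomized",
              random_state=seed)
    coords = pca.fit_transform(X)
    loadings = pca.components_.T  # genes × components
    # deterministic sign convention
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    coords = coords * flip
    loadings = loadings * flip
    return PCSpace(coords, loadings, pca.explained_variance_.copy())


def build_snn(pcs: PCSpace | np.ndarray, k_neighbors: int = 20,
              prune_threshold: float = 1.0 / 15.0) -> SNNGraph:
    """SNN graph: Jaccard overlap of kNN sets (self included), pruned."""
    X = pcs.coords if isinstance(pcs, PCSpace) else np.asarray(pcs)
    n = X.shape[0]
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(X)
    _, idx = nn.kneighbors(X)
    # neighbor sets include the cell itself
    rows = np.repeat(np.arange(n), k_neighbors + 1)
    cols = np.concatenate([idx, np.arange(n)[:, None]], axis=1).ravel()
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    A.data[:] = 1.0  # self may duplicate a reported neighbor
    A.sum_duplicates()
    A.data[:] = 1.0
    sizes = np.asarray(A.sum(axis=1)).ravel()
    inter = (A @ A.T).tocoo()
    union = sizes[inter.row] + sizes[inter.col] - inter.data
    w = inter.data / union
    keep = (w > prune_threshold) & (inter.row != inter.col)
    W = sp.csr_matrix((w[keep], (inter.row[keep], inter.col[keep])), shape=(n, n))
    W = W.maximum(W.T)
    return SNNGraph(W, k_neighbors, prune_threshold)


def graph_modularity(weights: sp.spmatrix, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Modularity Q = (1/2m) * sum_ij [A_ij - gamma*k_i*k_j/(2m)] delta(c_i,c_j),
    computed directly from the definition."""
    W = sp.csr_matrix(weights)
    labels = np.asarray(labels)
    k = np.asarray(W.sum(axis=1)).ravel()
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    q = 0.0
    for lab in np.unique(labels):
        mask = labels == lab
        sub = W[mask][:, mask]
        q += sub.sum() / two_m - resolution * (k[mask].sum() / two_m) ** 2
    return float(q)


def modularity_cluster(graph: SNNGraph, resolution: float = 0.8, seed: int = 0) -> ClusterAssignment:
    """Louvain community detection with resolution scaling of the null term.

    Deterministic given the seed; cluster labels are renumbered by decreasing
    community size. The reported modularity is recomputed from the definition
    on the returned partition.
    """
    W = graph.weights.tocoo()
    if W.shape[0] == 0 or W.nnz == 0:
        raise ValueError("empty graph")
    mask = W.row < W.col
    g = ig.Graph(
        n=W.shape[0],
        edges=list(zip(W.row[mask].tolist(), W.col[mask].tolist())),
        edge_attrs={"weight": W.data[mask].tolist()},
    )
    ig.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(weights="weight", resolution=resolution)
    labels = np.asarray(part.membership)
    # renumber by decreasing size, ties by first occurrence
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[v] for v in labels])
    q = graph_modularity(graph.weights, labels, resolution)
    return ClusterAssignment(labels, resolution, q)
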