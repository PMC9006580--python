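"""Single-lineage pseudotime by principal curve, adaptive binning, and a
per-gene pseudotime-association test.

The lineage is anchored at a user-chosen start cluster: a minimum spanning
tree over cluster centroids in PC space is traversed from the start cluster
to its farthest tip, and the resulting centroid path initializes an
iterative Hastie-Stuetzle principal-curve fit (project onto the curve,
smooth each coordinate against arc-length, repeat). Pseudotime is the
arc-length position on the converged curve, oriented so the start cluster
has the smallest median.

Cells are then divided into ``n_initial`` equal-width pseudotime bins and
adjacent bins with fewer than ``min_cells`` cells are merged (left-to-right
sweep, last bin merges leftward). Association of each gene with pseudotime
is tested by regressing normalized expression on a cubic B-spline basis of
pseudotime and testing the joint nullity of the spline coefficients (Wald
F-test under a Gaussian working model).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.interpolate import BSpline
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from scipy.stats import f as f_dist


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray          # per-cell arc-length, >= 0
    lineage: list                   # cluster labels from the start cluster
    curve: np.ndarray               # sample points of the fitted curve (m × d)
    n_iterations: int
    converged: bool


@dataclass
class Binning:
    edges: np.ndarray               # len = n_bins + 1
    bin_of_cell: np.ndarray         # per-cell bin index, 0-based
    counts: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1


def infer_lineage(pcs, clusters: np.ndarray, start_cluster) -> list:
    """Ordered cluster sequence: MST over cluster centroids, walked from the
    start cluster to the tip with the largest cumulative distance."""
    coords = pcs.coords if hasattr(pcs, "coords") else np.asarray(pcs)
    clusters = np.asarray(clusters)
    labels = list(pd.unique(clusters))
    if start_cluster not in labels:
        raise ValueError(f"start cluster {start_cluster!r} not present")
    if len(labels) < 2:
        return [start_cluster]
    cent = np.vstack([coords[clusters == lab].mean(axis=0) for lab in labels])
    D = cdist(cent, cent)
    mst = minimum_spanning_tree(D)
    adj = mst.toarray()
    adj = adj + adj.T
    start = labels.index(start_cluster)
    # farthest node by cumulative tree distance, path recovered by parents
    import heapq

    dist = {start: 0.0}
    parent = {start: None}
    heap = [(0.0, start)]
    while heap:
        d0, u = heapq.heappop(heap)
        if d0 > dist.get(u, np.inf):
            continue
        for v in np.flatnonzero(adj[u] > 0):
            nd = d0 + adj[u, v]
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                parent[v] = u
                heapq.heappush(heap, (nd, int(v)))
    end = max(dist, key=dist.get)
    path = []
    node = end
    while node is not None:
        path.append(node)
        node = parent[node]
    path.reverse()
    return [labels[i] for i in path]


def _project_onto_polyline(X: np.ndarray, P: np.ndarray):
    """Project points X (n×d) onto the polyline P (m×d).

    Returns (arc-length positions, squared distances)."""
    seg = P[1:] - P[:-1]                        # (m-1) × d
    seg_len2 = (seg**2).sum(axis=1)
    seg_len2 = np.maximum(seg_len2, 1e-300)
    # t parameter of the projection of every point on every segment
    diff = X[:, None, :] - P[None, :-1, :]      # n × (m-1) × d
    t = np.clip((diff * seg[None, :, :]).sum(axis=2) / seg_len2[None, :], 0.0, 1.0)
    proj = P[None, :-1, :] + t[:, :, None] * seg[None, :, :]
    d2 = ((X[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    n = len(X)
    seg_cumlen = np.concatenate([[0.0], np.cumsum(np.sqrt(seg_len2))])
    arc = seg_cumlen[best] + t[np.arange(n), best] * np.sqrt(seg_len2[best])
    return arc, d2[np.arange(n), best]


def _smooth_curve(lam: np.ndarray, X: np.ndarray, n_points: int,
                  span: float = 0.1) -> np.ndarray:
    """Local-average smoother: order cells by arc-length, take running means
    of each PC coordinate over an index window of ``span``·n cells, and read
    the curve off at ``n_points`` equally spaced rank positions."""
    order = np.argsort(lam, kind="stable")
    X_s = X[order]
    n = len(X_s)
    half = max(2, int(round(span * n / 2)))
    centers = np.linspace(0, n - 1, min(n_points, n)).round().astype(int)
    csum = np.vstack([np.zeros(X.shape[1]), np.cumsum(X_s, axis=0)])
    lo = np.maximum(centers - half, 0)
    hi = np.minimum(centers + half + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)[:, None]
    # drop consecutive duplicates so polyline segments have positive length
    keep = np.ones(len(out), bool)
    keep[1:] = (np.abs(np.diff(out, axis=0)).sum(axis=1) > 0)
    return out[keep] if keep.sum() >= 2 else out[:2]


def fit_principal_curve(
    pcs,
    cells: np.ndarray | None = None,
    clusters: np.ndarray | None = None,
    lineage: list | None = None,
    start_cluster=None,
    n_curve_points: int = 100,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> PseudotimeResult:
    """Hastie-Stuetzle principal curve initialized from the centroid path.

    ``cells`` optionally restricts the fit to a subset (boolean mask or index
    array); pseudotime is reported for those cells in their subset order.
    """
    coords = pcs.coords if hasattr(pcs, "coords") else np.asarray(pcs)
    if cells is not None:
        cells = np.asarray(cells)
        coords = coords[cells]
        clusters = None if clusters is None else np.asarray(clusters)[cells]
    n = len(coords)
    if n < 50:
        raise ValueError(f"principal curve needs >= 50 cells, got {n}")

    if lineage is None:
        if clusters is None or start_cluster is None:
            raise ValueError("provide either a lineage or (clusters, start_cluster)")
        lineage = infer_lineage(coords, clusters, start_cluster)
    if clusters is not None and len(lineage) >= 2:
        P = np.vstack([coords[clusters == lab].mean(axis=0) for lab in lineage])
    else:
        # fall back: initialize along the first principal direction
        u = coords - coords.mean(axis=0)
        w = np.linalg.svd(u, full_matrices=False)[2][0]
        t0 = u @ w
        P = np.vstack([coords[t0.argmin()], coords[t0.argmax()]])

    lam, d2 = _project_onto_polyline(coords, P)
    prev = d2.mean()
    converged = False
    it = 0
    curve = P
    for it in range(1, max_iter + 1):
        curve = _smooth_curve(lam, coords, n_curve_points)
        lam, d2 = _project_onto_polyline(coords, curve)
        cur = d2.mean()
        denom = max(prev, 1e-300)
        if abs(prev - cur) / denom < tol:
            converged = True
            break
        prev = cur
    if not converged:
        warnings.warn(f"principal curve did not converge in {max_iter} iterations")

    pt = lam - lam.min()
    if clusters is not None and start_cluster is None and lineage:
        start_cluster = lineage[0]
    if clusters is not None and start_cluster is not None:
        start_med = np.median(pt[clusters == start_cluster])
        other = clusters != start_cluster
        if other.any() and start_med > np.median(pt[other]):
            pt = pt.max() - pt
    if clusters is not None:
        # final cluster order along the fitted curve (the centroid-MST path is
        # only the initialization; near-tie MST topologies can skip a cluster)
        meds = {lab: float(np.median(pt[clusters == lab])) for lab in pd.unique(clusters)}
        lineage = sorted(meds, key=meds.get)
    return PseudotimeResult(pt, list(lineage), curve, it, converged)


def bin_cells(pt: PseudotimeResult | np.ndarray, n_initial: int = 20,
              min_cells: int = 100) -> Binning:
    """Equal-width initial bins over the pseudotime range, then merge any bin
    with fewer than ``min_cells`` cells into its right neighbor (the last bin
    merges leftward), sweeping left-to-right until stable."""
    t = pt.pseudotime if isinstance(pt, PseudotimeResult) else np.asarray(pt, float)
    if len(t) == 0:
        raise ValueError("no cells to bin")
    lo, hi = float(t.min()), float(t.max())
    if hi == lo:
        edges = np.array([lo, lo + 1e-12])
    else:
        edges = np.linspace(lo, hi, n_initial + 1)
    edges = list(edges)

    def counts_for(e):
        idx = np.clip(np.searchsorted(e, t, side="right") - 1, 0, len(e) - 2)
        return np.bincount(idx, minlength=len(e) - 1), idx

    counts, _ = counts_for(edges)
    while len(edges) > 2:
        merged = False
        i = 0
        while i < len(edges) - 1:
            counts, _ = counts_for(edges)
            if counts[i] < min_cells:
                if i < len(counts) - 1:
                    del edges[i + 1]   # merge with right neighbor
                else:
                    del edges[i]       # last bin merges leftward
                merged = True
                break
            i += 1
        if not merged:
            break
    counts, idx = counts_for(edges)
    return Binning(np.asarray(edges, float), idx, counts)


def _bspline_basis(t: np.ndarray, n_knots: int = 6, degree: int = 3) -> np.ndarray:
    """Cubic B-spline design matrix with interior knots at quantiles of t;
    the column space excludes the constant (intercept added by the caller)."""
    t = np.asarray(t, float)
    lo, hi = t.min(), t.max()
    n_interior = max(n_knots - degree - 1, 0)
    if n_interior > 0:
        interior = np.quantile(t, np.linspace(0, 1, n_interior + 2)[1:-1])
    else:
        interior = np.array([])
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    B = BSpline.design_matrix(np.clip(t, lo, hi), knots, degree).toarray()
    return B[:, 1:]  # drop one column; with the intercept, spans the same space


def association_test(lognorm, pt: PseudotimeResult | np.ndarray,
                     n_knots: int = 6) -> pd.DataFrame:
    """Per-gene Wald (F) test of the null that expression does not change
    along pseudotime, with Bonferroni adjustment over tested genes.

    ``lognorm`` may be a LogNormMatrix, sparse matrix or dense array
    (genes × cells over the trajectory cells, in pseudotime-vector order).
    """
    t = pt.pseudotime if isinstance(pt, PseudotimeResult) else np.asarray(pt, float)
    if hasattr(lognorm, "matrix"):
        Y = lognorm.matrix.toarray()
        symbols = lognorm.gene_symbols
    else:
        Y = lognorm.toarray() if sp.issparse(lognorm) else np.asarray(lognorm, float)
        symbols = np.arange(Y.shape[0])
    n = Y.shape[1]
    if n < 100:
        raise ValueError("association test needs >= 100 cells")
    if len(t) != n:
        raise ValueError("pseudotime length does not match cell count")

    B = _bspline_basis(t, n_knots)
    X = np.column_stack([np.ones(n), B])
    p_params = X.shape[1]
    q = B.shape[1]
    beta, _, rank, _ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    rss1 = (resid**2).sum(axis=0)
    rss0 = Y.var(axis=1) * n
    df2 = n - rank
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / q) / np.maximum(rss1 / df2, 1e-300)
    F = np.maximum(F, 0.0)
    pvals = f_dist.sf(F, q, df2)
    const = Y.std(axis=1) == 0
    pvals[const] = 1.0
    F[const] = 0.0
    n_tested = len(pvals)
    return pd.DataFrame(
        {
            "statistic": F,
            "df": q,
            "p_value": pvals,
            "p_adjusted": np.minimum(pvals * n_tested, 1.0),
        },
        index=pd.Index(symbols, name="gene"),
    )
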