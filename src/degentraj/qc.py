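"""Cell/gene quality control and marker-co-expression doublet removal.

Filtering follows the droplet-scRNA-seq convention: genes expressed in fewer
than ``min_cells_per_gene`` cells are dropped first, then cells are kept only
inside inclusive windows on detected genes (200-6000) and total transcripts
(1000-20,000). Doublets are flagged when a cell co-expresses the
high-specificity marker sets of more than one cluster type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix


@dataclass(frozen=True)
class QCThresholds:
    min_cells_per_gene: int = 3
    min_features: int = 200
    max_features: int = 6000
    min_umi: int = 1000
    max_umi: int = 20000

    def __post_init__(self):
        if self.min_features >= self.max_features:
            raise ValueError("min_features must be < max_features")
        if self.min_umi >= self.max_umi:
            raise ValueError("min_umi must be < max_umi")


def cell_metrics(counts: CountMatrix, mito_prefix: str = "mt-") -> pd.DataFrame:
    """Per-cell n_features, n_umi and pct_mito (percentage, 0-100)."""
    X = counts.matrix.tocsc()
    n_features = X.getnnz(axis=0)
    n_umi = np.asarray(X.sum(axis=0)).ravel()
    mito = np.char.startswith(counts.gene_symbols.astype(str), mito_prefix)
    if not mito.any():
        warnings.warn(f"no gene symbol starts with {mito_prefix!r}; pct_mito set to 0")
        mito_umi = np.zeros_like(n_umi)
    else:
        mito_umi = np.asarray(X[mito].sum(axis=0)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_umi > 0, 100.0 * mito_umi / np.maximum(n_umi, 1), 0.0)
    return pd.DataFrame(
        {"n_features": n_features, "n_umi": n_umi, "pct_mito": pct},
        index=pd.Index(counts.barcodes, name="barcode"),
    )


def apply_qc_filters(
    counts: CountMatrix,
    metrics: pd.DataFrame | None = None,
    thr: QCThresholds = QCThresholds(),
    mito_prefix: str = "mt-",
) -> CountMatrix:
    """Gene filter first (expressed in >= min_cells_per_gene cells), then cell
    windows on features/UMI (inclusive bounds). The returned matrix's ``log``
    records how many genes and cells were dropped.
    """
    gene_cells = counts.matrix.getnnz(axis=1)
    keep_genes = gene_cells >= thr.min_cells_per_gene
    filtered = counts.subset_genes(keep_genes)
    # metrics are recomputed after the gene filter so the cell windows see the
    # surviving genes only (also makes the whole filter idempotent)
    m = cell_metrics(filtered, mito_prefix)
    keep_cells = (
        (m["n_features"].to_numpy() >= thr.min_features)
        & (m["n_features"].to_numpy() <= thr.max_features)
        & (m["n_umi"].to_numpy() >= thr.min_umi)
        & (m["n_umi"].to_numpy() <= thr.max_umi)
    )
    if not keep_cells.any():
        raise ValueError(
            "QC removed every cell; review thresholds "
            f"(features {thr.min_features}-{thr.max_features}, UMI {thr.min_umi}-{thr.max_umi})"
        )
    out = filtered.subset_cells(keep_cells)
    out.log["genes_dropped"] = int((~keep_genes).sum())
    out.log["cells_dropped"] = int((~keep_cells).sum())
    return out


def _cluster_auc(ranks: np.ndarray, in_cluster: np.ndarray) -> np.ndarray:
    """Per-gene AUC of expression for cluster-vs-rest via the rank-sum
    identity; ``ranks`` are average ranks of each gene across all cells."""
    n1 = int(in_cluster.sum())
    n2 = ranks.shape[1] - n1
    r1 = ranks[:, in_cluster].sum(axis=1)
    u = r1 - n1 * (n1 + 1) / 2.0
    return u / (n1 * n2)


def find_power_markers(
    lognorm: np.ndarray,
    gene_symbols: np.ndarray,
    clusters: np.ndarray,
    top_n: int = 10,
    min_auc: float = 0.8,
    max_pct_out: float = 0.2,
) -> pd.DataFrame:
    """Per-cluster marker genes ranked by cluster-vs-rest AUC.

    A gene qualifies as a power marker for a cluster when its AUC >= ``min_auc``
    and it is detected in at most ``max_pct_out`` of cells outside the cluster.
    Returns a DataFrame with columns cluster, gene, auc, pct_in, pct_out.
    """
    lognorm = np.asarray(lognorm)
    clusters = np.asarray(clusters)
    labels = np.unique(clusters)
    if len(labels) < 2:
        raise ValueError("need >= 2 clusters to rank markers")
    detected = lognorm > 0
    from scipy.stats import rankdata

    ranks = rankdata(lognorm, axis=1)  # average ranks handle the many zero ties
    rows = []
    for lab in labels:
        mask = clusters == lab
        if mask.sum() < 3:
            warnings.warn(f"cluster {lab!r} has < 3 cells; skipped for marker ranking")
            continue
        auc = _cluster_auc(ranks, mask)
        pct_in = detected[:, mask].mean(axis=1)
        pct_out = detected[:, ~mask].mean(axis=1)
        ok = (auc >= min_auc) & (pct_out <= max_pct_out)
        idx = np.flatnonzero(ok)
        idx = idx[np.argsort(-auc[idx], kind="stable")][:top_n]
        for g in idx:
            rows.append((lab, gene_symbols[g], float(auc[g]), float(pct_in[g]), float(pct_out[g])))
    return pd.DataFrame(rows, columns=["cluster", "gene", "auc", "pct_in", "pct_out"])


def merge_clusters_into_types(
    lognorm: np.ndarray,
    clusters: np.ndarray,
    corr_threshold: float = 0.8,
    feature_rows: np.ndarray | None = None,
) -> np.ndarray:
    """Merge transcriptomically similar clusters into cluster *types*.

    Clusters whose mean expression profiles (Spearman, over ``feature_rows``
    or all genes) correlate above ``corr_threshold`` are joined by connected
    components, so e.g. several stage-clusters of one cell type form a single
    type. Marker-based doublet flagging operates on these types: stages of
    one cell type share their defining markers, which would otherwise leave
    the type without any cluster-specific marker. Returns a per-cell type
    label ("T<i>").
    """
    from scipy.sparse.csgraph import connected_components
    from scipy.stats import spearmanr

    lognorm = np.asarray(lognorm)
    if feature_rows is not None:
        lognorm = lognorm[np.asarray(feature_rows)]
    clusters = np.asarray(clusters)
    labels = np.unique(clusters)
    means = np.column_stack([lognorm[:, clusters == lab].mean(axis=1) for lab in labels])
    k = len(labels)
    adj = np.zeros((k, k), bool)
    for i in range(k):
        for j in range(i + 1, k):
            rho = spearmanr(means[:, i], means[:, j]).statistic
            adj[i, j] = adj[j, i] = bool(rho >= corr_threshold)
    n_comp, comp = connected_components(sp.csr_matrix(adj), directed=False)
    comp_of = {lab: comp[i] for i, lab in enumerate(labels)}
    return np.array([f"T{comp_of[c]}" for c in clusters], dtype=object)


def flag_coexpression_doublets(
    lognorm: np.ndarray,
    gene_symbols: np.ndarray,
    clusters: np.ndarray,
    markers: pd.DataFrame,
    min_markers: int = 3,
    min_foreign_clusters: int = 1,
) -> np.ndarray:
    """Flag cells that express the marker repertoires of multiple cluster types.

    A cell is flagged when, beyond its own cluster, there are at least
    ``min_foreign_clusters`` other clusters for which it expresses at least
    ``min_markers`` of that cluster's power markers above zero.
    """
    if min_markers <= 0:
        raise ValueError("min_markers must be >= 1")
    if markers.empty:
        raise ValueError("marker table is empty")
    lognorm = np.asarray(lognorm)
    clusters = np.asarray(clusters)
    sym_index = {s: i for i, s in enumerate(gene_symbols)}
    flags = np.zeros(lognorm.shape[1], dtype=bool)
    marker_rows = {
        lab: np.array([sym_index[g] for g in grp["gene"] if g in sym_index], dtype=int)
        for lab, grp in markers.groupby("cluster")
    }
    # per cluster: how many of its markers each cell expresses
    hit_counts = {
        lab: (lognorm[rows] > 0).sum(axis=0) if len(rows) else np.zeros(lognorm.shape[1], int)
        for lab, rows in marker_rows.items()
    }
    n_foreign = np.zeros(lognorm.shape[1], dtype=int)
    for lab, counts_ in hit_counts.items():
        foreign = clusters != lab
        n_foreign += foreign & (counts_ >= min_markers)
    flags = n_foreign >= min_foreign_clusters
    return flags
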