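"""Pseudotime-binned expression profiles and k-means pattern classification.

For every gene of interest the mean normalized expression is computed in
each pseudotime bin, each gene's bin profile is z-scaled across bins
(population standard deviation), and the z-profiles are clustered with
k-means (k=4). Each centroid is then given a semantic label describing its
pseudotemporal shape: downregulation, early permanent upregulation, early
transient upregulation, or late upregulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .trajectory import Binning

PATTERN_LABELS = ("down", "early_permanent_up", "early_transient_up", "late_up")


@dataclass
class BinProfileMatrix:
    means: pd.DataFrame      # genes × bins, mean normalized expression
    z: pd.DataFrame          # genes × bins, row-scaled (population sd)
    constant: np.ndarray     # flag: rows constant across bins (z set to 0)


@dataclass
class PatternAssignment:
    assignments: pd.DataFrame   # per gene: kmeans_cluster, label, distance
    centroids: np.ndarray       # k × bins
    centroid_labels: list
    seed: int


def binned_profiles(lognorm, binning: Binning, genes: np.ndarray) -> BinProfileMatrix:
    """Per-bin mean normalized expression for the given genes, plus the
    row-wise z-scaled companion matrix."""
    genes = np.asarray(genes)
    if len(genes) == 0:
        raise ValueError("gene list is empty")
    if hasattr(lognorm, "matrix"):
        X = lognorm.matrix
        symbols = np.asarray(lognorm.gene_symbols)
    else:
        X = lognorm
        symbols = np.arange(X.shape[0])
    X = X.toarray() if sp.issparse(X) else np.asarray(X, float)
    order = {s: i for i, s in enumerate(symbols)}
    missing = [g for g in genes if g not in order]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    rows = np.array([order[g] for g in genes])

    nb = binning.n_bins
    M = np.zeros((len(rows), nb))
    for b in range(nb):
        mask = binning.bin_of_cell == b
        M[:, b] = X[rows][:, mask].mean(axis=1)
    mu = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, keepdims=True)  # population sd across bins
    constant = (sd.ravel() == 0)
    if constant.any():
        warnings.warn(f"{constant.sum()} gene(s) constant across bins; z-rows set to 0")
    Z = np.where(sd > 0, (M - mu) / np.maximum(sd, 1e-300), 0.0)
    cols = [f"bin{b + 1}" for b in range(nb)]
    gidx = pd.Index(genes, name="gene")
    return BinProfileMatrix(
        pd.DataFrame(M, index=gidx, columns=cols),
        pd.DataFrame(Z, index=gidx, columns=cols),
        constant,
    )


def label_profile(z: np.ndarray, first_frac: float = 1 / 3, final_frac: float = 0.5) -> str:
    """Semantic label for one z-profile, by shape rules applied in order:

    1. "down" — first-third mean exceeds last-third mean and the maximum sits
       in the first third (a decreasing profile);
    2. "early_transient_up" — maximum in the first half but the final bin has
       fallen below ``final_frac`` of the maximum;
    3. "early_permanent_up" — risen to at least half its total span by the
       midpoint and still at >= ``final_frac`` of the maximum in the final bin;
    4. "late_up" — maximum in the last third.

    When no rule fires, the profile is matched to the nearest canonical
    template (in that order) by correlation.
    """
    z = np.asarray(z, float)
    nb = len(z)
    third = max(1, nb // 3)
    amax = int(z.argmax())
    span = z.max() - z.min()
    starts_at_top = span == 0 or z[0] >= z.max() - 0.25 * span
    if z[:third].mean() > z[-third:].mean() and amax < third and starts_at_top:
        return "down"
    if amax < nb / 2 and z[-1] < final_frac * z.max():
        return "early_transient_up"
    mid = nb // 2
    rise = z.max() - z[0]
    if rise > 0 and (z[mid] - z[0]) >= 0.5 * rise and z[-1] >= final_frac * z.max():
        return "early_permanent_up"
    if amax >= 2 * nb / 3:
        return "late_up"
    # fallback: nearest canonical template
    t = np.linspace(0, 1, nb)
    templates = {
        "down": -t,
        "early_permanent_up": 1 / (1 + np.exp(-12 * (t - 0.35))),
        "early_transient_up": np.exp(-((t - 0.4) ** 2) / (2 * 0.13**2)),
        "late_up": 1 / (1 + np.exp(-14 * (t - 0.75))),
    }
    best, best_r = PATTERN_LABELS[0], -np.inf
    for lab in PATTERN_LABELS:
        tmpl = templates[lab]
        ts = tmpl.std()
        r = -np.inf if z.std() == 0 or ts == 0 else float(np.corrcoef(z, tmpl)[0, 1])
        if r > best_r:
            best, best_r = lab, r
    return best


def classify_patterns(profiles: BinProfileMatrix, k: int = 4, seed: int = 0,
                      n_init: int = 10) -> PatternAssignment:
    """k-means over z-profiles with semantic centroid labeling.

    Initialization is seeded k-means++ and independent of gene order.
    """
    Z = profiles.z.to_numpy()
    if Z.shape[0] < k:
        raise ValueError(f"need >= {k} genes for k={k} clustering")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    centroids = km.cluster_centers_
    # renumber clusters canonically (by centroid argmax position, then mean)
    order = np.lexsort((centroids.mean(axis=1), centroids.argmax(axis=1)))
    remap = np.zeros(k, int)
    remap[order] = np.arange(k)
    labels_idx = remap[km.labels_]
    centroids = centroids[order]
    centroid_labels = [label_profile(c) for c in centroids]
    if len(set(centroid_labels)) < k:
        warnings.warn("two k-means centroids map to the same semantic label")
    dist = np.linalg.norm(Z - centroids[labels_idx], axis=1)
    assignments = pd.DataFrame(
        {
            "kmeans_cluster": labels_idx,
            "label": [centroid_labels[i] for i in labels_idx],
            "distance": dist,
        },
        index=profiles.z.index,
    )
    return PatternAssignment(assignments, centroids, centroid_labels, seed)
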