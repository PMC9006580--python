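"""Cross-group transcriptome similarity and relative qPCR expression.

Similarity between cell groups (e.g. mutant cones vs degenerating rods) is
Spearman's rank correlation of the per-group mean normalized expression over
a fixed feature set — by convention the 5000 most variable genes of the main
dataset. Relative expression from qPCR Ct values uses the 2^-ddCt method:
dCt = Ct_target - Ct_reference per sample, ddCt referenced to the mean dCt
of a calibrator group, relative expression = 2^-ddCt.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr


def group_mean_expression(lognorm, groups: np.ndarray, features: np.ndarray | None = None) -> pd.DataFrame:
    """Gene×group matrix of mean normalized expression.

    ``groups`` assigns every cell a group label; cells labeled None/NaN are
    excluded. ``features`` restricts (and orders) the gene rows.
    """
    if hasattr(lognorm, "matrix"):
        X = lognorm.matrix
        symbols = np.asarray(lognorm.gene_symbols)
    else:
        X = lognorm
        symbols = np.arange(X.shape[0])
    X = X.toarray() if sp.issparse(X) else np.asarray(X, float)
    groups = np.asarray(groups, dtype=object)
    valid = np.array([g is not None and g == g for g in groups])

    if features is not None:
        features = np.asarray(features)
        order = {s: i for i, s in enumerate(symbols)}
        missing = [f for f in features if f not in order]
        if missing:
            raise KeyError(f"features absent from matrix: {missing[:5]}")
        rows = np.array([order[f] for f in features])
        X = X[rows]
        symbols = features
    cols = {}
    for lab in pd.unique(groups[valid]):
        mask = valid & (groups == lab)
        cols[lab] = X[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=pd.Index(symbols, name="gene"))


def spearman_similarity(means: pd.DataFrame) -> pd.DataFrame:
    """Symmetric group×group Spearman correlation matrix (average-rank ties).

    Constant columns yield undefined correlations, reported as NaN."""
    if means.shape[1] < 2:
        raise ValueError("need >= 2 groups")
    if means.shape[0] < 3:
        raise ValueError("need >= 3 features")
    cols = means.columns
    k = len(cols)
    out = np.ones((k, k))
    const = means.std(axis=0).to_numpy() == 0
    if const.any():
        warnings.warn("constant group column(s); correlations reported as NaN")
    for i in range(k):
        for j in range(i + 1, k):
            if const[i] or const[j]:
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = spearmanr(means.iloc[:, i], means.iloc[:, j]).statistic
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=cols, columns=cols)


def relative_expression_ddct(
    ct: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """2^-ddCt relative expression from a tidy Ct table.

    ``ct`` needs columns sample, group, gene, ct; replicate Ct values per
    (sample, gene) are averaged before dCt. Returns one row per
    (sample, group, gene != reference) with dct, ddct and rel_expr; the
    calibrator group's mean relative expression is 1 by construction
    (geometric mean when its dCt values differ).
    """
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    mean_ct = ct.groupby(["sample", "group", "gene"], sort=False)["ct"].mean().reset_index()
    ref = mean_ct[mean_ct["gene"] == reference_gene].set_index("sample")["ct"]
    targets = mean_ct[mean_ct["gene"] != reference_gene].copy()
    no_ref = set(targets["sample"]) - set(ref.index)
    if no_ref:
        raise ValueError(f"reference gene {reference_gene!r} missing for sample(s) {sorted(no_ref)}")
    targets["dct"] = targets["ct"].to_numpy() - ref.loc[targets["sample"]].to_numpy()
    cal = targets[targets["group"] == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    cal_mean = cal.groupby("gene")["dct"].mean()
    genes_wo_cal = set(targets["gene"]) - set(cal_mean.index)
    if genes_wo_cal:
        raise ValueError(f"no calibrator measurements for gene(s) {sorted(genes_wo_cal)}")
    targets["ddct"] = targets["dct"].to_numpy() - cal_mean.loc[targets["gene"]].to_numpy()
    targets["rel_expr"] = 2.0 ** (-targets["ddct"])
    return targets[["sample", "group", "gene", "dct", "ddct", "rel_expr"]].reset_index(drop=True)
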