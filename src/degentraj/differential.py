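"""Pairwise Wilcoxon rank-sum differential expression.

Fold changes follow the droplet-toolkit convention: natural-log fold change
between group means of the back-transformed normalized values with a +1
pseudocount,
    avg_logFC = ln(mean(expm1(x_A)) + 1) - ln(mean(expm1(x_B)) + 1).
Positive values mean higher expression in group A. P-values come from the
two-sided Wilcoxon rank-sum test (exact enumeration when both groups have at
most ``exact_limit`` cells and the data are tie-free, otherwise the normal
approximation with tie correction), adjusted by Bonferroni over the genes
actually tested after the detection/fold-change pre-filter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu, rankdata, norm


def _wilcoxon_normal_p(Y_a: np.ndarray, Y_b: np.ndarray) -> np.ndarray:
    """Vectorized two-sided rank-sum p (normal approximation, tie-corrected)."""
    n1, n2 = Y_a.shape[1], Y_b.shape[1]
    Y = np.concatenate([Y_a, Y_b], axis=1)
    ranks = rankdata(Y, axis=1)
    u = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per gene
    tie_term = np.zeros(Y.shape[0])
    for g in range(Y.shape[0]):
        _, cnt = np.unique(Y[g], return_counts=True)
        tie_term[g] = (cnt**3 - cnt).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - mu) / np.sqrt(np.maximum(var, 1e-300))
    p = 2.0 * norm.sf(np.abs(z))
    p[var <= 0] = 1.0  # all values tied
    return np.minimum(p, 1.0)


def wilcoxon_de(
    lognorm,
    group_a: np.ndarray,
    group_b: np.ndarray,
    min_pct: float = 0.1,
    logfc_floor: float = 0.25,
    exact_limit: int = 25,
    exclude_prefixes: tuple = (),
) -> pd.DataFrame:
    """Differential expression between two disjoint cell sets.

    ``group_a``/``group_b`` are boolean masks or index arrays over the cells
    of ``lognorm`` (LogNormMatrix, sparse or dense genes×cells).
    ``exclude_prefixes`` drops genes whose symbol starts with any given prefix
    (e.g. ``("Hba-", "Hbb-")`` to remove hemoglobin transcripts) from the
    reported table. Returns a DataFrame sorted by p_value with columns
    avg_logFC, pct_1, pct_2, p_value, p_adjusted.
    """
    if hasattr(lognorm, "matrix"):
        X = lognorm.matrix
        symbols = np.asarray(lognorm.gene_symbols)
    else:
        X = lognorm
        symbols = np.arange(np.asarray(X).shape[0] if not sp.issparse(X) else X.shape[0])
    X = X.toarray() if sp.issparse(X) else np.asarray(X, float)

    n_cells = X.shape[1]
    a = np.zeros(n_cells, bool); a[np.asarray(group_a)] = True
    b = np.zeros(n_cells, bool); b[np.asarray(group_b)] = True
    if (a & b).any():
        raise ValueError("groups overlap")
    if a.sum() < 3 or b.sum() < 3:
        raise ValueError("each group needs >= 3 cells")

    Ya, Yb = X[:, a], X[:, b]
    pct1 = (Ya > 0).mean(axis=1)
    pct2 = (Yb > 0).mean(axis=1)
    mean_a = np.expm1(Ya).mean(axis=1)
    mean_b = np.expm1(Yb).mean(axis=1)
    logfc = np.log(mean_a + 1.0) - np.log(mean_b + 1.0)

    tested = (np.maximum(pct1, pct2) >= min_pct) & (np.abs(logfc) >= logfc_floor)
    if exclude_prefixes:
        sym = symbols.astype(str)
        excl = np.zeros(len(sym), bool)
        for pref in exclude_prefixes:
            excl |= np.char.startswith(sym, pref)
        tested &= ~excl
    idx = np.flatnonzero(tested)
    if len(idx) == 0:
        warnings.warn("no genes pass the DE pre-filter; returning an empty table")
        return pd.DataFrame(
            columns=["avg_logFC", "pct_1", "pct_2", "p_value", "p_adjusted"]
        ).rename_axis("gene")

    n1, n2 = int(a.sum()), int(b.sum())
    if n1 <= exact_limit and n2 <= exact_limit:
        pvals = np.empty(len(idx))
        for k, g in enumerate(idx):
            ya, yb = Ya[g], Yb[g]
            ties = len(np.unique(np.concatenate([ya, yb]))) < n1 + n2
            if ties:
                pvals[k] = _wilcoxon_normal_p(ya[None, :], yb[None, :])[0]
            else:
                pvals[k] = mannwhitneyu(ya, yb, alternative="two-sided", method="exact").pvalue
    else:
        pvals = _wilcoxon_normal_p(Ya[idx], Yb[idx])

    n_tested = len(idx)
    out = pd.DataFrame(
        {
            "avg_logFC": logfc[idx],
            "pct_1": pct1[idx],
            "pct_2": pct2[idx],
            "p_value": pvals,
            "p_adjusted": np.minimum(pvals * n_tested, 1.0),
        },
        index=pd.Index(symbols[idx], name="gene"),
    )
    return out.sort_values("p_value", kind="stable")
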