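"""Log-normalization, variable-gene selection and scaling with UMI regression.

Normalized value = ln(1 + scale_factor * count / cell_total). Variable genes
are picked by the classic mean/dispersion window: per-gene mean and
variance-to-mean ratio of the back-transformed normalized values, dispersion
z-scored within 20 equal-frequency mean bins, window mean in [0.1, 8] and
standardized dispersion > 1, capped at the 5000 most dispersed. Scaling
regresses each gene on total UMI (OLS) and standardizes residuals to mean 0,
variance 1, clipped at +/-10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix


@dataclass
class LogNormMatrix:
    """Gene×cell log-normalized expression (sparse), with gene symbols,
    barcodes and the per-cell totals of the underlying counts."""

    matrix: sp.csr_matrix
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    cell_totals: np.ndarray
    scale_factor: float

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def log_normalize(counts: CountMatrix, scale_factor: float = 10000.0) -> LogNormMatrix:
    """ln(1 + scale_factor * c / total) per entry; sparsity preserved."""
    totals = np.asarray(counts.matrix.sum(axis=0)).ravel().astype(float)
    if (totals == 0).any():
        bad = counts.barcodes[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; filter before normalizing")
    X = counts.matrix.tocsc().astype(float)
    X = X.multiply(scale_factor / totals[None, :]).tocsr()
    X.data = np.log1p(X.data)
    return LogNormMatrix(X, counts.gene_symbols.copy(), counts.barcodes.copy(), totals, scale_factor)


def select_variable_genes(
    lognorm: LogNormMatrix,
    mean_lo: float = 0.1,
    mean_hi: float = 8.0,
    disp_min: float = 1.0,
    n_top: int = 5000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Mean/dispersion variable-gene selection.

    Returns a per-gene DataFrame (mean, dispersion, dispersion_std, selected)
    indexed by gene symbol; ties in dispersion are broken by gene order so the
    selection is deterministic.
    """
    X = lognorm.matrix
    if X.shape[0] < 100:
        warnings.warn("fewer than 100 genes; variable-gene statistics are unstable")
    # back-transform: expm1 of the normalized values
    E = X.copy()
    E.data = np.expm1(E.data)
    n = X.shape[1]
    mean = np.asarray(E.sum(axis=1)).ravel() / n
    sq = E.copy()
    sq.data = sq.data**2
    var = np.asarray(sq.sum(axis=1)).ravel() / n - mean**2
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)

    # standardize dispersion within equal-frequency mean bins
    disp_std = np.zeros_like(disp)
    nonzero = mean > 0
    if nonzero.sum() > 0:
        k = min(n_bins, max(1, len(np.unique(mean[nonzero]))))
        if k < n_bins:
            warnings.warn(f"only {k} distinct means; using {k} bins instead of {n_bins}")
        try:
            bins = pd.qcut(mean[nonzero], k, labels=False, duplicates="drop")
        except ValueError:
            bins = np.zeros(nonzero.sum(), dtype=int)
        d = disp[nonzero]
        out = np.zeros_like(d)
        for b in np.unique(bins):
            sel = bins == b
            mu, sd = d[sel].mean(), d[sel].std()
            out[sel] = (d[sel] - mu) / sd if sd > 0 else 0.0
        disp_std[nonzero] = out

    qualifies = (mean >= mean_lo) & (mean <= mean_hi) & (disp_std > disp_min)
    selected = np.zeros(len(mean), dtype=bool)
    idx = np.flatnonzero(qualifies)
    if len(idx) > n_top:
        idx = idx[np.argsort(-disp_std[idx], kind="stable")[:n_top]]
    selected[idx] = True
    return pd.DataFrame(
        {"mean": mean, "dispersion": disp, "dispersion_std": disp_std, "selected": selected},
        index=pd.Index(lognorm.gene_symbols, name="gene"),
    )


def scale_and_regress(
    lognorm: LogNormMatrix,
    genes: np.ndarray | None = None,
    clip_max: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Regress each gene's normalized expression on total UMI, standardize the
    residuals to mean 0 / variance 1 and clip at ``clip_max``.

    Returns (scaled gene×cell dense array, gene symbols used).
    """
    symbols = lognorm.gene_symbols
    if genes is not None:
        genes = np.asarray(genes)
        missing = set(genes) - set(symbols)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        order = {s: i for i, s in enumerate(symbols)}
        rows = np.array([order[g] for g in genes])
    else:
        rows = np.arange(len(symbols))
    Y = lognorm.matrix[rows].toarray()
    x = lognorm.cell_totals.astype(float)
    n = len(x)
    xc = x - x.mean()
    ssx = float((xc**2).sum())
    if ssx == 0:
        warnings.warn("total-UMI covariate is constant; standardizing without regression")
        resid = Y - Y.mean(axis=1, keepdims=True)
    else:
        beta = (Y @ xc) / ssx
        resid = Y - Y.mean(axis=1, keepdims=True) - beta[:, None] * xc[None, :]
    sd = resid.std(axis=1)
    scaled = np.where(sd[:, None] > 1e-12, resid / np.maximum(sd, 1e-300)[:, None], 0.0)
    np.clip(scaled, -clip_max, clip_max, out=scaled)
    return scaled, symbols[rows]
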