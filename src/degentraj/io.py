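"""Sparse gene×cell count container and 10x-style triplet IO.

The on-disk convention follows the 10x Genomics CellRanger output layout:
a MatrixMarket coordinate file with genes as rows and cells as columns,
a features TSV (feature id, symbol) and a barcodes TSV (one barcode per
line), all uncompressed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class TripletParseError(ValueError):
    """Raised when the MTX/features/barcodes triplet is inconsistent."""


@dataclass
class CountMatrix:
    """Integer gene×cell counts with feature and barcode identifiers.

    ``matrix`` is stored CSR with genes as rows; ``features`` is a DataFrame
    with columns ``id`` and ``symbol`` (one row per gene); ``barcodes`` is an
    array of cell identifiers.
    """

    matrix: sp.csr_matrix
    features: pd.DataFrame
    barcodes: np.ndarray
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.matrix.shape[0] != len(self.features):
            raise ValueError(
                f"feature table has {len(self.features)} rows but matrix has "
                f"{self.matrix.shape[0]} gene rows"
            )
        if self.matrix.shape[1] != len(self.barcodes):
            raise ValueError(
                f"{len(self.barcodes)} barcodes but matrix has "
                f"{self.matrix.shape[1]} cell columns"
            )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def gene_symbols(self) -> np.ndarray:
        return self.features["symbol"].to_numpy()

    def subset_cells(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(
            self.matrix[:, idx], self.features.reset_index(drop=True), self.barcodes[idx]
        )

    def subset_genes(self, mask_or_index) -> "CountMatrix":
        idx = np.asarray(mask_or_index)
        return CountMatrix(
            self.matrix[idx],
            self.features.iloc[np.arange(self.n_genes)[idx] if idx.dtype == bool else idx]
            .reset_index(drop=True),
            self.barcodes,
        )

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.matrix.shape == other.matrix.shape
            and (self.matrix != other.matrix).nnz == 0
            and self.features["id"].tolist() == other.features["id"].tolist()
            and self.features["symbol"].tolist() == other.features["symbol"].tolist()
            and list(self.barcodes) == list(other.barcodes)
        )


def write_10x_triplet(counts: CountMatrix, directory: str | os.PathLike) -> None:
    """Write ``matrix.mtx`` / ``features.tsv`` / ``barcodes.tsv`` into *directory*."""
    os.makedirs(directory, exist_ok=True)
    coo = counts.matrix.tocoo()
    scipy.io.mmwrite(
        os.path.join(directory, "matrix.mtx"),
        sp.coo_matrix((coo.data.astype(np.int64), (coo.row, coo.col)), shape=coo.shape),
        field="integer",
    )
    counts.features[["id", "symbol"]].to_csv(
        os.path.join(directory, "features.tsv"), sep="\t", header=False, index=False
    )
    pd.Series(counts.barcodes).to_csv(
        os.path.join(directory, "barcodes.tsv"), sep="\t", header=False, index=False
    )


def read_10x_triplet(directory: str | os.PathLike) -> CountMatrix:
    """Read a triplet written by :func:`write_10x_triplet` (or CellRanger-style).

    Raises :class:`TripletParseError` when the matrix dimensions disagree with
    the TSV line counts, naming the offending file.
    """
    mtx_path = os.path.join(directory, "matrix.mtx")
    feat_path = os.path.join(directory, "features.tsv")
    bc_path = os.path.join(directory, "barcodes.tsv")
    for p in (mtx_path, feat_path, bc_path):
        if not os.path.exists(p):
            raise TripletParseError(f"missing file: {p}")
    try:
        mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # malformed header / body
        raise TripletParseError(f"{mtx_path}: {exc}") from exc
    mat = sp.csr_matrix(mat)
    feats = pd.read_csv(feat_path, sep="\t", header=None, dtype=str)
    if feats.shape[1] < 2:
        feats[1] = feats[0]
    features = pd.DataFrame({"id": feats[0], "symbol": feats[1]})
    with open(bc_path) as fh:
        barcodes = np.array([ln.strip() for ln in fh if ln.strip() != ""], dtype=object)
    if mat.shape[0] != len(features):
        raise TripletParseError(
            f"{feat_path}: {len(features)} features but matrix declares {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise TripletParseError(
            f"{bc_path}: {len(barcodes)} barcodes but matrix declares {mat.shape[1]} columns"
        )
    return CountMatrix(mat, features, barcodes)
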