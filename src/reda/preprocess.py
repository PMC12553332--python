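"""TF-IDF normalization and LSI embedding of the peak-by-cell count matrix.

scATAC-seq counts are near-binary and extremely sparse (typically 1–10% of
peaks detected per cell), so the standard dimensionality reduction is latent
semantic indexing: log-TF-IDF weighting followed by a truncated SVD.  The
first LSI component tracks per-cell sequencing depth and is dropped by
default, retaining components 2..n as the embedding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.utils.extmath import randomized_svd

from .io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["LsiEmbedding", "tfidf", "lsi"]


@dataclass
class LsiEmbedding:
    """Low-dimensional cell coordinates from LSI (rows ordered as cells)."""

    coords: np.ndarray            # cells x d
    dims_used: np.ndarray         # 1-based indices of retained SVD components
    variance: np.ndarray          # singular values of retained components

    def __post_init__(self) -> None:
        if self.coords.shape[1] < 2:
            raise ValueError("embedding needs at least 2 dimensions")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("embedding contains NaN/Inf")


def tfidf(
    counts: CountMatrix,
    scale: float = 1e4,
    binarize: bool = True,
) -> sp.csr_matrix:
    """Signac-style log-TF-IDF transform of a peak-by-cell count matrix.

    Entry (p, c) becomes ``log(1 + TF * IDF * scale)`` with
    ``TF = count[p,c] / colsum[c]`` and ``IDF = n_cells / n_cells_detecting[p]``.
    Counts are binarized first by default, reflecting the near-binary nature
    of scATAC-seq. Zero entries stay zero, so sparsity is preserved.  Peaks
    detected in no cell are dropped (their IDF is undefined).

    Raises ``ValueError`` if any cell has zero total count.
    """
    mat = counts.counts.tocsc().astype(float)
    if binarize:
        mat.data = (mat.data > 0).astype(float)
    col_totals = np.asarray(mat.sum(axis=0)).ravel()
    if np.any(col_totals == 0):
        bad = np.flatnonzero(col_totals == 0)
        raise ValueError(
            f"{bad.size} cell(s) with zero total count (first: "
            f"{counts.cell_barcodes[bad[0]]}); filter them before TF-IDF"
        )
    detect = np.diff(sp.csr_matrix(counts.counts).astype(bool).indptr)
    keep = detect > 0
    if not keep.all():
        logger.warning("dropping %d peak(s) detected in zero cells", (~keep).sum())
    mat = sp.csr_matrix(mat)[keep]
    detect = detect[keep]
    n_cells = mat.shape[1]

    mat = mat.tocoo()
    tf = mat.data / col_totals[mat.col]
    idf = n_cells / detect[mat.row]
    data = np.log1p(tf * idf * scale)
    out = sp.csr_matrix((data, (mat.row, mat.col)), shape=mat.shape)
    return out


def lsi(
    tfidf_matrix: sp.spmatrix,
    n_components: int = 30,
    drop_first: bool = True,
    random_state: int = 0,
) -> LsiEmbedding:
    """Truncated SVD of the TF-IDF matrix, returning cell coordinates.

    With the defaults (``n_components=30``, ``drop_first=True``) the embedding
    retains components 2–30.  The SVD is randomized but deterministic for a
    fixed ``random_state``.
    """
    mat = sp.csr_matrix(tfidf_matrix)
    n_peaks, n_cells = mat.shape
    if n_components >= min(n_peaks, n_cells):
        raise ValueError(
            f"n_components={n_components} must be < min(n_peaks, n_cells)="
            f"{min(n_peaks, n_cells)}; choose a smaller value"
        )
    # SVD of the cells x peaks orientation: U rows are cells.
    u, s, _ = randomized_svd(
        mat.T, n_components=n_components, random_state=random_state, n_iter=7
    )
    if s[-1] <= 1e-12 * s[0]:
        raise ValueError(
            f"matrix rank below n_components={n_components}; choose a smaller value"
        )
    coords = u * s
    start = 1 if drop_first else 0
    dims = np.arange(start, n_components) + 1  # 1-based component indices
    return LsiEmbedding(coords[:, start:], dims, s[start:])
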