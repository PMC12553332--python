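"""Shared-nearest-neighbor (SNN) cell–cell graph construction.

Edge weight between two cells is the Jaccard overlap of their k-nearest-
neighbor sets (each set including the cell itself, the Seurat/Signac
convention), pruned below a threshold.  The adjacency is exactly symmetric
with a zero diagonal, and every cell is guaranteed a positive degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["SnnGraph", "knn", "snn_from_knn", "save_graph", "load_graph"]

DEFAULT_K = 20
DEFAULT_PRUNE = 1.0 / 15.0

# Above this many cells, exact brute-force kNN gives way to a tree index.
EXACT_KNN_MAX_CELLS = 50_000


@dataclass
class SnnGraph:
    """Symmetric weighted SNN adjacency with weights in [0, 1], zero diagonal."""

    adjacency: sp.csr_matrix
    k_neighbors: int
    prune_threshold: float
    approximate: bool = False

    def __post_init__(self) -> None:
        a = sp.csr_matrix(self.adjacency)
        if (a != a.T).nnz:
            raise ValueError("adjacency is not symmetric")
        if a.nnz and a.data.min() < 0:
            raise ValueError("negative edge weights")
        if a.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal")
        deg = np.asarray(a.sum(axis=1)).ravel()
        if np.any(deg == 0):
            raise ValueError("graph has isolated cells (zero degree)")
        self.adjacency = a

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


def knn(coords: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """k nearest cells (Euclidean, self excluded) for every cell.

    Ties in distance are broken in favor of the lower cell index; the result
    is an (M, k) integer array.  Exact brute-force search is used up to
    ``EXACT_KNN_MAX_CELLS`` cells, a KD-tree beyond that.
    """
    coords = np.asarray(coords, float)
    m = coords.shape[0]
    if k >= m:
        raise ValueError(f"k={k} must be < number of cells ({m})")
    if m > EXACT_KNN_MAX_CELLS:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
        idx = nn.kneighbors(return_distance=False)
        return idx[:, :k] if idx.shape[1] > k else idx
    out = np.empty((m, k), dtype=np.int64)
    chunk = max(1, int(2e7) // max(m, 1))
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        d = cdist(coords[lo:hi], coords)
        d[np.arange(hi - lo), np.arange(lo, hi)] = np.inf  # exclude self
        # stable sort on distance keeps lower indices first among ties
        order = np.argsort(d, axis=1, kind="stable")
        out[lo:hi] = order[:, :k]
    return out


def snn_from_knn(neighbors: np.ndarray, prune: float = DEFAULT_PRUNE) -> SnnGraph:
    """Jaccard SNN graph from kNN index lists.

    Each cell's neighborhood is its k neighbors plus itself; the weight of
    edge (i, j) is |Ni ∩ Nj| / |Ni ∪ Nj|.  Weights below ``prune`` are
    removed.  A cell left isolated by pruning has its strongest pre-prune
    edge restored (with a warning) so every cell keeps positive degree.
    """
    neighbors = np.asarray(neighbors)
    m, k = neighbors.shape
    size = k + 1  # neighborhood includes the anchor cell
    rows = np.repeat(np.arange(m), size)
    cols = np.concatenate([neighbors, np.arange(m)[:, None]], axis=1).ravel()
    ind = sp.csr_matrix((np.ones(rows.size), (rows, cols)), shape=(m, m))
    inter = (ind @ ind.T).tocoo()
    jac = inter.data / (2 * size - inter.data)
    full = sp.csr_matrix((jac, (inter.row, inter.col)), shape=(m, m))
    full.setdiag(0)
    full.eliminate_zeros()

    pruned = full.copy()
    pruned.data[pruned.data < prune] = 0
    pruned.eliminate_zeros()

    deg = np.asarray((pruned != 0).sum(axis=1)).ravel()
    isolated = np.flatnonzero(deg == 0)
    if isolated.size:
        logger.warning(
            "restoring strongest pre-prune edge for %d isolated cell(s)", isolated.size
        )
        pruned = pruned.tolil()
        fl = full.tolil()
        for i in isolated:
            row = np.asarray(fl.rows[i])
            dat = np.asarray(fl.data[i])
            j = row[np.argmax(dat)]
            w = dat.max()
            pruned[i, j] = w
            pruned[j, i] = w
        pruned = pruned.tocsr()

    pruned = pruned.maximum(pruned.T)  # exact symmetry
    return SnnGraph(pruned, k_neighbors=k, prune_threshold=prune)


def save_graph(graph: SnnGraph, path: str | Path) -> None:
    scipy.io.mmwrite(str(path), sp.coo_matrix(graph.adjacency), symmetry="symmetric")


def load_graph(path: str | Path, k_neighbors: int = 0, prune: float = 0.0) -> SnnGraph:
    adj = sp.csr_matrix(scipy.io.mmread(str(path)))
    adj = adj.maximum(adj.T)
    return SnnGraph(adj, k_neighbors=k_neighbors, prune_threshold=prune)
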