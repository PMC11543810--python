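"""kNN cell-graph construction and symmetric normalisation.

The transformer learns all-pair cell relations on its own; a precomputed
kNN graph is an optional structural bias.  Each cell is connected to its
k nearest distinct cells by Euclidean distance in expression space, the
directed edge set is symmetrised by union, and propagation uses the
symmetrically normalised operator D^{-1/2} A D^{-1/2} with the
convention that zero-degree nodes contribute nothing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .io_preprocess import ExpressionMatrix

__all__ = ["CellGraph", "build_knn_graph", "normalize_adjacency",
           "write_edge_list", "read_edge_list"]

# above this size exact all-pairs distance matrices get expensive;
# fall back to a tree/approximate neighbor backend
EXACT_SEARCH_MAX_N = 8192


@dataclass(frozen=True)
class CellGraph:
    """Binary, symmetric, zero-diagonal adjacency over cells."""

    adjacency: sp.csr_matrix

    def __post_init__(self):
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.nnz and not np.all(np.isin(a.data, (0, 1))):
            raise ValueError("adjacency must be binary")
        if (abs(a - a.T)).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")

    @property
    def n_cells(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(np.int64)

    def induced(self, idx: np.ndarray) -> "CellGraph":
        """Subgraph on the given node indices (adjacency submatrix)."""
        idx = np.asarray(idx)
        return CellGraph(self.adjacency[np.ix_(idx, idx)].tocsr())


def build_knn_graph(x: ExpressionMatrix | np.ndarray, k: int) -> CellGraph:
    """Union-symmetrised exact kNN graph on Euclidean distance.

    Ties in distance are broken toward the lower cell index; no
    self-edges.  Exact brute-force search is used up to
    ``EXACT_SEARCH_MAX_N`` cells, a tree-based backend beyond.
    """
    if isinstance(x, ExpressionMatrix):
        if x.stage not in ("normalized", "hvg"):
            raise ValueError(f"graph expects normalized or hvg input, got {x.stage}")
        feats = x.dense()
    else:
        feats = np.asarray(x, dtype=np.float64)
    n = feats.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"require 1 <= k < n_cells, got k={k}, n={n}")
    if np.isnan(feats).any():
        raise ValueError("NaN in features")

    if n <= EXACT_SEARCH_MAX_N:
        dist = cdist(feats, feats)
        np.fill_diagonal(dist, np.inf)
        # stable sort on distance keeps lower index first among ties
        nbrs = np.argsort(dist, axis=1, kind="stable")[:, :k]
    else:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(feats)
        idx = nn.kneighbors(feats, return_distance=False)
        nbrs = np.empty((n, k), dtype=np.int64)
        for i in range(n):
            row = idx[i][idx[i] != i][:k]
            nbrs[i] = row

    rows = np.repeat(np.arange(n), k)
    cols = nbrs.ravel()
    directed = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    union = directed.maximum(directed.T)
    union.data[:] = 1.0
    return CellGraph(union.tocsr())


def normalize_adjacency(g: CellGraph, add_self_loops: bool = False) -> np.ndarray:
    """Symmetrically normalised propagation matrix D^{-1/2} A D^{-1/2}.

    With ``add_self_loops`` the identity is added to A (and degrees
    recomputed) first.  Zero-degree nodes get zero rows/columns.
    """
    a = g.adjacency.astype(np.float64)
    if add_self_loops:
        a = a + sp.eye(g.n_cells, format="csr")
    deg = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        dinv = 1.0 / np.sqrt(deg)
    dinv[~np.isfinite(dinv)] = 0.0
    out = a.multiply(dinv[:, None]).multiply(dinv[None, :])
    return np.asarray(out.todense())


def write_edge_list(g: CellGraph, path: str | os.PathLike) -> None:
    """Export as TSV: one ``i<TAB>j`` line (0-based, i<j) per undirected edge."""
    coo = sp.triu(g.adjacency, k=1).tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        for i, j in zip(coo.row[order], coo.col[order]):
            fh.write(f"{i}\t{j}\n")


def read_edge_list(path: str | os.PathLike, n_cells: int) -> CellGraph:
    rows, cols = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            i, j = map(int, line.split())
            rows += [i, j]
            cols += [j, i]
    a = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_cells, n_cells)
    )
    a.data[:] = 1.0
    return CellGraph(a)
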