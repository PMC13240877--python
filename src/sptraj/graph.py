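"""Spatial neighborhood graph from the alpha complex.

The spatial graph G=(V,E) connects cells that are Voronoi-adjacent *and*
whose shared Voronoi facet comes within a radius ``delta`` of both sites —
the 1-skeleton of the alpha complex at scale delta.  We compute it from the
Delaunay triangulation: a Delaunay edge belongs to the alpha complex iff its
filtration radius (half-length when the diametral ball is empty — the
Gabriel case — otherwise the smallest circumradius of an incident triangle)
is at most delta.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError
from sklearn.neighbors import NearestNeighbors

log = logging.getLogger(__name__)

__all__ = ["SpatialGraph", "estimate_radius_delta", "build_alpha_adjacency"]


@dataclass
class SpatialGraph:
    """Sparse symmetric binary adjacency over cells."""

    adjacency: sp.csr_matrix
    radius_delta: float

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    def edge_list(self) -> np.ndarray:
        """(n_edges, 2) array of 0-based index pairs with i < j."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return np.column_stack([coo.row, coo.col])

    def export_edges(self, path: str) -> None:
        np.savetxt(path, self.edge_list(), fmt="%d", delimiter="\t")

    def neighbors(self, i: int) -> np.ndarray:
        return self.adjacency.indices[
            self.adjacency.indptr[i]:self.adjacency.indptr[i + 1]
        ]


def estimate_radius_delta(coords: np.ndarray, k: int = 6) -> float:
    """Scale parameter delta: mean over points of the mean k-NN distance."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if not (n > k >= 1):
        raise ValueError(f"need n > k >= 1, got n={n}, k={k}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    delta = float(dist[:, 1:].mean())
    if delta == 0.0:
        raise ValueError("degenerate coordinates: all points identical")
    if (dist[:, 1] == 0).any():
        warnings.warn("duplicate coordinates present; they contribute zero distance")
    return delta


def _circumradius(a, b, c):
    la, lb, lc = (np.linalg.norm(b - c), np.linalg.norm(a - c),
                  np.linalg.norm(a - b))
    area2 = abs((b[0] - a[0]) * (c[1] - a[1]) - (c[0] - a[0]) * (b[1] - a[1]))
    if area2 == 0:
        return np.inf
    return la * lb * lc / (2.0 * area2)


def delaunay_edge_filtration(coords: np.ndarray):
    """Delaunay edges with their alpha-complex filtration radii.

    Returns (edges, filt): edges is (E,2) int with i<j, filt the radius at
    which each edge enters the alpha complex.
    """
    coords = np.asarray(coords, dtype=float)
    tri = Delaunay(coords)
    edge_tris = {}
    for simplex in tri.simplices:
        for a in range(3):
            i, j = sorted((simplex[a], simplex[(a + 1) % 3]))
            edge_tris.setdefault((i, j), []).append(simplex[(a + 2) % 3])
    edges, filt = [], []
    for (i, j), opposite in edge_tris.items():
        pi, pj = coords[i], coords[j]
        mid = 0.5 * (pi + pj)
        r = 0.5 * np.linalg.norm(pi - pj)
        # Gabriel test: for a Delaunay edge only the opposite vertices of the
        # incident triangles can fall inside the diametral ball.
        gabriel = all(np.linalg.norm(coords[o] - mid) >= r * (1 - 1e-12)
                      for o in opposite)
        if gabriel:
            f = r
        else:
            f = min(_circumradius(pi, pj, coords[o]) for o in opposite)
        edges.append((i, j))
        filt.append(f)
    return np.array(edges, dtype=int), np.array(filt, dtype=float)


def _knn_fallback(coords: np.ndarray, k: int = 6) -> sp.csr_matrix:
    n = coords.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    A = sp.coo_matrix((np.ones(rows.size), (rows, cols)), shape=(n, n))
    A = ((A + A.T) > 0).astype(np.int8)
    A.setdiag(0)
    A.eliminate_zeros()
    return A.tocsr()


def build_alpha_adjacency(coords: np.ndarray, delta: float) -> SpatialGraph:
    """Alpha-complex 1-skeleton at scale ``delta`` as a sparse adjacency.

    Degenerate geometry (collinear points, too few points) falls back to a
    symmetric k-NN graph (k=6) with a logged warning.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if delta <= 0:
        raise ValueError("delta must be positive")
    try:
        if n < 3:
            raise QhullError("fewer than 3 points")
        edges, filt = delaunay_edge_filtration(coords)
    except QhullError:
        log.warning("degenerate geometry; falling back to symmetric k-NN graph")
        warnings.warn("degenerate geometry: using k-NN fallback graph")
        return SpatialGraph(_knn_fallback(coords), float(delta))
    keep = edges[filt <= delta]
    data = np.ones(2 * len(keep), dtype=np.int8)
    rows = np.concatenate([keep[:, 0], keep[:, 1]]) if len(keep) else np.array([], int)
    cols = np.concatenate([keep[:, 1], keep[:, 0]]) if len(keep) else np.array([], int)
    A = sp.coo_matrix((data[: rows.size], (rows, cols)), shape=(n, n)).tocsr()
    return SpatialGraph(A, float(delta))
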