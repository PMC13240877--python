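"""Spatial density, adaptive fusion weights, and the fused cost matrix.

Local cell density is a Gaussian-kernel score, exponentiated to sharpen
contrast, then min-max normalized to [0,1].  A reverse affine map turns
density into a per-cell spatial weight alpha in [alpha_min, alpha_max]
(dense regions -> alpha_min: the joint embedding dominates; sparse regions
-> alpha_max: raw spatial proximity dominates).  Cells whose local geometry
is untrustworthy (tissue edge, hole-adjacent, poorly connected) receive a
fixed conservative weight alpha_prot instead.  The fused cost is the
row-indexed convex combination M_ij = alpha~_i * ds(i,j) +
(1 - alpha~_i) * dg(i,j) of max-normalized spatial and embedding distances;
M is generally asymmetric because alpha~ belongs to the source cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform
from sklearn.neighbors import NearestNeighbors

from .graph import SpatialGraph

__all__ = [
    "DensityField", "WeightMap", "FusedCost",
    "estimate_density", "normalize_density", "default_bandwidth",
    "map_density_to_alpha", "detect_low_confidence", "build_weight_map",
    "fuse_distances",
]

EPS = 1e-10


@dataclass
class DensityField:
    rho_hat: np.ndarray
    bandwidth: float
    rho: Optional[np.ndarray] = None
    epsilon: float = EPS


@dataclass
class WeightMap:
    alpha: np.ndarray
    alpha_min: float
    alpha_max: float
    alpha_prot: float
    protected: np.ndarray
    alpha_tilde: np.ndarray


@dataclass
class FusedCost:
    ds: np.ndarray
    dg: np.ndarray
    M: np.ndarray


def default_bandwidth(coords: np.ndarray) -> float:
    """Scott's-rule bandwidth for 2-D KDE: n^(-1/6) x mean coordinate std.

    A regional-scale bandwidth, so the density field reflects tissue-level
    crowding rather than nearest-neighbor sampling noise.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    b = n ** (-1.0 / 6.0) * float(coords.std(axis=0).mean())
    if b <= 0:
        raise ValueError("degenerate coordinates: zero spread")
    return b


def estimate_density(coords: np.ndarray, bandwidth: float = None) -> DensityField:
    """rho_hat_i = exp( (1/(n b)) sum_j K(||s_i - s_j|| / b) ).

    K is the standard Gaussian kernel K(u) = exp(-u^2/2)/sqrt(2 pi); the
    self term j = i is included.
    """
    coords = np.asarray(coords, dtype=float)
    if bandwidth is None:
        bandwidth = default_bandwidth(coords)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    n = coords.shape[0]
    D = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    K = np.exp(-0.5 * (D / bandwidth) ** 2) / np.sqrt(2.0 * np.pi)
    rho_hat = np.exp(K.sum(axis=1) / (n * bandwidth))
    return DensityField(rho_hat=rho_hat, bandwidth=float(bandwidth))


def normalize_density(field: DensityField) -> DensityField:
    """Min-max map to [0,1] with an epsilon-guarded denominator."""
    r = field.rho_hat
    field.rho = (r - r.min()) / (r.max() - r.min() + field.epsilon)
    return field


def map_density_to_alpha(rho: np.ndarray, alpha_min: float = 0.2,
                         alpha_max: float = 0.8) -> np.ndarray:
    """alpha = alpha_min + (1 - rho) (alpha_max - alpha_min).

    The unique affine reverse map: rho -> 1 gives alpha_min, rho -> 0 gives
    alpha_max.
    """
    if alpha_min > alpha_max:
        raise ValueError("alpha_min must not exceed alpha_max")
    if not (0 <= alpha_min and alpha_max <= 1):
        raise ValueError("alpha bounds must lie in [0, 1]")
    return alpha_min + (1.0 - np.asarray(rho)) * (alpha_max - alpha_min)


def detect_low_confidence(coords: np.ndarray, graph: SpatialGraph,
                          hole_factor: float = 3.0,
                          min_degree: int = 2) -> np.ndarray:
    """Flag cells whose local density estimate is untrustworthy.

    A cell is low-confidence if it (1) lies on the convex hull (tissue edge,
    unbounded Voronoi cell), (2) sits next to a hole: mean distance to its
    graph neighbors exceeds hole_factor x the global median neighbor
    distance, or (3) has graph degree below min_degree.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    mask = np.zeros(n, dtype=bool)
    try:
        hull = ConvexHull(coords)
        mask[hull.vertices] = True
    except QhullError:
        mask[:] = True          # fully degenerate layout: nothing is interior
    deg = graph.degrees()
    mask |= deg < min_degree
    edges = graph.edge_list()
    if len(edges):
        elen = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
        med = np.median(elen)
        mean_nb = np.zeros(n)
        for i in range(n):
            nb = graph.neighbors(i)
            if nb.size:
                mean_nb[i] = np.linalg.norm(coords[nb] - coords[i], axis=1).mean()
        mask |= (deg > 0) & (mean_nb > hole_factor * med)
    return mask


def build_weight_map(coords: np.ndarray, graph: SpatialGraph,
                     bandwidth: float = None, alpha_min: float = 0.2,
                     alpha_max: float = 0.8, alpha_prot: float = None,
                     hole_factor: float = 3.0, min_degree: int = 2,
                     adaptive: bool = True) -> WeightMap:
    """Density -> alpha -> protection, in one call.

    ``adaptive=False`` reproduces the constant-weight ablation:
    alpha~ = (alpha_min + alpha_max)/2 everywhere, no protection.
    """
    n = np.asarray(coords).shape[0]
    if not adaptive:
        const = 0.5 * (alpha_min + alpha_max)
        a = np.full(n, const)
        return WeightMap(a, alpha_min, alpha_max, const,
                         np.zeros(n, dtype=bool), a.copy())
    if alpha_prot is None:
        # low confidence means the density estimate is untrustworthy: fall
        # back to the neutral midpoint rather than either extreme
        alpha_prot = 0.5 * (alpha_min + alpha_max)
    field = normalize_density(estimate_density(coords, bandwidth))
    alpha = map_density_to_alpha(field.rho, alpha_min, alpha_max)
    protected = detect_low_confidence(coords, graph, hole_factor, min_degree)
    alpha_tilde = np.where(protected, alpha_prot, alpha)
    return WeightMap(alpha, alpha_min, alpha_max, alpha_prot,
                     protected, alpha_tilde)


def fuse_distances(Z: np.ndarray, coords: np.ndarray,
                   alpha_tilde: np.ndarray) -> FusedCost:
    """Max-normalized spatial/embedding distances and their fused cost M."""
    alpha_tilde = np.asarray(alpha_tilde, dtype=float)
    if ((alpha_tilde < 0) | (alpha_tilde > 1)).any():
        raise ValueError("alpha_tilde must lie in [0, 1]")
    ds = squareform(pdist(np.asarray(coords, dtype=float)))
    dg = squareform(pdist(np.asarray(Z, dtype=float)))
    if ds.max() == 0:
        raise ValueError("degenerate normalization: all coordinates identical")
    ds = ds / ds.max()
    if dg.max() > 0:
        dg = dg / dg.max()
    else:
        warnings.warn("all embedding vectors identical; dg is zero")
    M = alpha_tilde[:, None] * ds + (1.0 - alpha_tilde[:, None]) * dg
    return FusedCost(ds=ds, dg=dg, M=M)
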