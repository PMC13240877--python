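"""Per-cell velocity vectors, grid interpolation, and streamlines.

Each cell's neighborhood is the union of its spatial k-NN (size kp) and its
embedding k-NN (size ke).  The velocity is the mean, over that union, of
unit displacement directions weighted by the signed normalized transition
probability: +p_ij toward later-pseudotime neighbors, -p_ij toward earlier
ones.  Velocities are interpolated onto a regular grid with an adaptive
Gaussian kernel whose bandwidth scales with the box size and grid
resolution, and streamlines integrate the bilinear grid field with RK4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from sklearn.neighbors import NearestNeighbors

__all__ = ["NeighborSets", "VelocityField", "GridField", "neighbor_union",
           "cell_velocity", "grid_interpolate", "streamlines"]

EPS = 1e-10


@dataclass
class NeighborSets:
    spatial: List[np.ndarray]
    embed: List[np.ndarray]
    union: List[np.ndarray]


@dataclass
class VelocityField:
    v: np.ndarray                   # (n, 2)
    p_norm: Optional[List[np.ndarray]] = None


@dataclass
class GridField:
    grid_x: np.ndarray              # (g,)
    grid_y: np.ndarray              # (g,)
    grid_v: np.ndarray              # (g, g, 2), indexed [iy, ix]
    sigma: float
    b_res: int
    Q: float
    e: float

    @property
    def grid_points(self) -> np.ndarray:
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        return np.column_stack([gx.ravel(), gy.ravel()])


def _knn_lists(V: np.ndarray, k: int) -> List[np.ndarray]:
    n = V.shape[0]
    if k == 0:
        return [np.array([], dtype=int) for _ in range(n)]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(V)
    _, idx = nn.kneighbors(V)
    out = []
    for i in range(n):
        row = idx[i][idx[i] != i][:k]
        out.append(row)
    return out


def neighbor_union(coords: np.ndarray, Z: np.ndarray,
                   kp: int = 15, ke: int = 15) -> NeighborSets:
    """Union of spatial and embedding k-NN sets, self excluded."""
    coords = np.asarray(coords, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n = coords.shape[0]
    if kp < 0 or ke < 0 or kp + ke < 1:
        raise ValueError("need kp, ke >= 0 with kp + ke >= 1")
    if kp >= n or ke >= n:
        raise ValueError(f"kp/ke must be < n={n}")
    spatial = _knn_lists(coords, kp)
    embed = _knn_lists(Z, ke)
    union = [np.union1d(s, e).astype(int) for s, e in zip(spatial, embed)]
    return NeighborSets(spatial=spatial, embed=embed, union=union)


def cell_velocity(neighbors: NeighborSets, P, tau: np.ndarray,
                  coords: np.ndarray) -> VelocityField:
    """v_i = (1/|N_i|) sum_{j in N_i} gamma_ij (s_j - s_i)/(||s_j - s_i|| + eps).

    gamma_ij = +p_ij when tau_j >= tau_i else -p_ij, with p_ij the transition
    probability row-normalized over the neighbor set N_i.
    """
    Pm = np.asarray(P.P if hasattr(P, "P") else P, dtype=float)
    coords = np.asarray(coords, dtype=float)
    tau = np.asarray(tau, dtype=float)
    n = coords.shape[0]
    v = np.zeros((n, 2))
    p_norm: List[np.ndarray] = []
    for i in range(n):
        N = neighbors.union[i]
        if N.size == 0:
            p_norm.append(np.array([]))
            continue
        p_raw = Pm[i, N]
        tot = p_raw.sum()
        if tot <= 0:
            warnings.warn(f"cell {i}: zero total neighbor probability; v=0")
            p_norm.append(np.zeros(N.size))
            continue
        p = p_raw / tot
        p_norm.append(p)
        disp = coords[N] - coords[i]
        norm = np.linalg.norm(disp, axis=1) + EPS
        sign = np.where(tau[N] >= tau[i], 1.0, -1.0)
        # mean over N_i of signed, probability-weighted unit directions
        v[i] = ((sign * p)[:, None] * disp / norm[:, None]).sum(axis=0) / N.size
    return VelocityField(v=v, p_norm=p_norm)


def grid_interpolate(field: VelocityField, coords: np.ndarray,
                     b_res: int = 50, Q: float = 1.0, e: float = 0.5) -> GridField:
    """Adaptive-Gaussian-kernel average of cell velocities on a regular grid.

    Grid is floor(b*Q) x floor(b*Q) over the coordinate bounding box; the
    kernel bandwidth is  sigma = ((Xmax-Xmin)+(Ymax-Ymin))/2 *
    1/(floor(b*Q)-1) * e,  and the denominator max(1, sum phi) damps the
    far field instead of renormalizing it.
    """
    coords = np.asarray(coords, dtype=float)
    g = int(np.floor(b_res * Q))
    if g < 2:
        raise ValueError(f"grid resolution floor(b*Q)={g} must be >= 2")
    xmin, ymin = coords.min(axis=0)
    xmax, ymax = coords.max(axis=0)
    sigma = ((xmax - xmin) + (ymax - ymin)) / 2.0 / (g - 1) * e
    if sigma <= 0:
        raise ValueError("degenerate bounding box")
    gx = np.linspace(xmin, xmax, g)
    gy = np.linspace(ymin, ymax, g)
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    phi = np.exp(-d2 / (2.0 * sigma ** 2))
    den = np.maximum(1.0, phi.sum(axis=1))
    gv = (phi @ field.v) / den[:, None]
    return GridField(grid_x=gx, grid_y=gy, grid_v=gv.reshape(g, g, 2),
                     sigma=float(sigma), b_res=b_res, Q=Q, e=e)


def streamlines(grid: GridField, seed_every: int = 2, step_frac: float = 0.5,
                max_steps: int = 500, min_speed_frac: float = 1e-3
                ) -> List[np.ndarray]:
    """RK4 integral curves of the bilinear-interpolated grid field.

    Seeds sit on every ``seed_every``-th grid node; integration stops on
    leaving the box, dropping below ``min_speed_frac`` of the maximum grid
    speed, or after ``max_steps`` steps.  All-zero fields give no lines.
    """
    speed = np.linalg.norm(grid.grid_v, axis=2)
    vmax = speed.max()
    if vmax <= 0:
        return []
    interp = RegularGridInterpolator(
        (grid.grid_y, grid.grid_x), grid.grid_v,
        bounds_error=False, fill_value=None)

    def f(p):
        return interp(np.array([[p[1], p[0]]]))[0]

    hx = grid.grid_x[1] - grid.grid_x[0]
    hy = grid.grid_y[1] - grid.grid_y[0]
    h = step_frac * min(hx, hy)
    floor = min_speed_frac * vmax
    xmin, xmax = grid.grid_x[0], grid.grid_x[-1]
    ymin, ymax = grid.grid_y[0], grid.grid_y[-1]
    lines = []
    for iy in range(0, len(grid.grid_y), seed_every):
        for ix in range(0, len(grid.grid_x), seed_every):
            p = np.array([grid.grid_x[ix], grid.grid_y[iy]], dtype=float)
            pts = [p.copy()]
            for _ in range(max_steps):
                v1 = f(p)
                s = np.linalg.norm(v1)
                if s < floor:
                    break
                k1 = v1 / s
                k2v = f(p + 0.5 * h * k1)
                k2 = k2v / (np.linalg.norm(k2v) + 1e-30)
                k3v = f(p + 0.5 * h * k2)
                k3 = k3v / (np.linalg.norm(k3v) + 1e-30)
                k4v = f(p + h * k3)
                k4 = k4v / (np.linalg.norm(k4v) + 1e-30)
                p = p + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
                if not (xmin <= p[0] <= xmax and ymin <= p[1] <= ymax):
                    break
                pts.append(p.copy())
            if len(pts) > 2:
                lines.append(np.array(pts))
    return lines
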