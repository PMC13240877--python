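"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the implementation's code paths: the alpha-complex
oracle works straight from the Voronoi/disk definition by scanning the
perpendicular bisector of each pair, and the transport oracle is a naive
alternating-scaling Sinkhorn fixed point in the probability domain.
"""

import numpy as np


def alpha_edges_bruteforce(pts: np.ndarray, delta: float,
                           n_samples: int = 2001) -> set:
    """Edges (i,j), i<j, of the alpha complex at scale delta.

    (i,j) is an edge iff some point x equidistant from p_i and p_j lies in
    both Voronoi cells (no other site strictly closer) with |x - p_i| <=
    delta.  Feasible x live on the perpendicular bisector within a bounded
    segment, which is scanned densely.
    """
    pts = np.asarray(pts, dtype=float)
    n = len(pts)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = pts[i], pts[j]
            d = np.linalg.norm(pj - pi)
            if d == 0 or delta < d / 2:
                continue
            mid = 0.5 * (pi + pj)
            u = (pj - pi) / d
            perp = np.array([-u[1], u[0]])
            smax = np.sqrt(delta ** 2 - (d / 2) ** 2)
            for s in np.linspace(-smax, smax, n_samples):
                x = mid + s * perp
                r = np.linalg.norm(x - pi)
                if (np.linalg.norm(pts - x, axis=1) >= r - 1e-9).all():
                    edges.add((i, j))
                    break
    return edges


def naive_sinkhorn(C: np.ndarray, gamma: float, n_iter: int = 50_000,
                   tol: float = 1e-13) -> np.ndarray:
    """Plain alternating marginal scaling u <- a/(Kv), v <- b/(K^T u)."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    a = b = np.full(n, 1.0 / n)
    K = np.exp(-C / gamma)
    u = np.ones(n)
    v = np.ones(n)
    for _ in range(n_iter):
        u_new = a / (K @ v)
        v = b / (K.T @ u_new)
        if np.abs(u_new - u).max() < tol:
            u = u_new
            break
        u = u_new
    return u[:, None] * K * v[None, :]


def enumerate_min_path(P: np.ndarray, source: int, sink: int):
    """Exhaustive least-action path by enumerating all simple paths."""
    from itertools import permutations

    n = P.shape[0]
    pmax = P.max()
    best = (np.inf, None)
    others = [k for k in range(n) if k not in (source, sink)]
    for r in range(len(others) + 1):
        for mid in permutations(others, r):
            path = [source, *mid, sink]
            cost = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if P[a, b] <= 0:
                    ok = False
                    break
                cost += -np.log(P[a, b] / pmax)
            if ok and cost < best[0]:
                best = (cost, path)
    return best
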