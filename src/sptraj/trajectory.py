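"""Pseudotime, lineage paths, and pseudotime-dependent genes.

Starting cells come from prior knowledge, either by cell-type label or as
the k nearest cells to a known morphogenesis center.  Each cell accumulates
transition probability from the start set, O_i = sum_{j in S} P_ji; ranking
the cells by O and normalizing the rank gives pseudotime tau in [0, 1].
Because accumulated mass is largest *near* the start set while tau ~ 0 must
mark the initial state, the default orientation anchors the start set early
(flipping tau -> 1 - tau when the start cells' mean tau lands above 0.5);
the raw ascending-rank convention is available via ``orient="raw"``.

Lineage paths are least-action paths: shortest paths under edge cost
-log(P_ij / max P) on the union of spatial-graph edges and each cell's top-q
transition partners.  Trend genes are scored by penalized-spline GAM fits of
expression against tau (deviance explained).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import networkx as nx
import numpy as np
import pandas as pd

from .transport import TransitionMatrix, row_stochastic

__all__ = ["StartSet", "PseudotimeResult", "LineagePath", "select_start",
           "pseudotime", "least_action_path", "trend_genes"]


@dataclass
class StartSet:
    indices: np.ndarray
    mode: str                       # "by_type" | "by_coord"
    target_type: Optional[str] = None
    center: Optional[np.ndarray] = None
    k: Optional[int] = None


@dataclass
class PseudotimeResult:
    O: np.ndarray                   # accumulated probability from the start set
    r: np.ndarray                   # integer ranks
    tau: np.ndarray                 # normalized pseudotime in [0, 1]
    start: StartSet
    flipped: bool = False


@dataclass
class LineagePath:
    waypoints: List[int]
    cost: float


def select_start(ds, mode: str, target_type: str = None,
                 center=None, k: int = None) -> StartSet:
    """Start cells by cell-type label or by proximity to a center point."""
    if mode == "by_type":
        if ds.cell_type is None:
            raise ValueError("by_type start selection needs cell_type labels")
        labels = np.asarray(ds.cell_type).astype(str)
        if target_type is None:
            raise ValueError("target_type required for by_type")
        idx = np.flatnonzero(labels == str(target_type))
        if idx.size == 0:
            raise ValueError(
                f"label {target_type!r} absent; available: "
                f"{sorted(set(labels.tolist()))}")
        return StartSet(idx, "by_type", target_type=target_type)
    if mode == "by_coord":
        center = np.asarray(center, dtype=float).ravel()
        if center.shape != (2,):
            raise ValueError("center must be a 2-vector")
        if k is None:
            k = 1
        n = ds.coords.shape[0]
        if k > n:
            raise ValueError(f"k={k} exceeds n={n}")
        d = np.linalg.norm(ds.coords - center, axis=1)
        # stable sort => equidistant ties resolve to the lowest index
        idx = np.argsort(d, kind="stable")[:k]
        return StartSet(np.sort(idx), "by_coord", center=center, k=k)
    raise ValueError(f"unknown mode {mode!r}")


def pseudotime(P: TransitionMatrix, start: StartSet,
               orient: str = "auto") -> PseudotimeResult:
    """Accumulated-probability pseudotime.

    O_i = sum_{j in S} P_ji, ranks ascending with stable index tie-break,
    tau = rank / (N - 1).  ``orient="auto"`` flips tau to place the start
    set early; ``orient="raw"`` keeps the ascending-rank convention.
    """
    Pm = np.asarray(P.P if hasattr(P, "P") else P, dtype=float)
    S = np.asarray(start.indices, dtype=int)
    if S.size == 0:
        raise ValueError("empty start set")
    O = Pm[S, :].sum(axis=0)
    if np.allclose(O, O[0]):
        warnings.warn("accumulated probabilities are constant; ranking by index")
    n = O.size
    order = np.argsort(O, kind="stable")
    r = np.empty(n, dtype=int)
    r[order] = np.arange(n)
    tau = r / (n - 1)
    flipped = False
    if orient == "auto" and tau[S].mean() >= 0.5:
        tau = 1.0 - tau
        r = (n - 1) - r
        flipped = True
    return PseudotimeResult(O=O, r=r, tau=tau, start=start, flipped=flipped)


def transition_graph(P, spatial_graph=None, top_q: int = 30) -> nx.DiGraph:
    """Directed graph with edge cost -log(P_ij / max P).

    Candidate edges are the union of spatial-graph edges (both directions)
    and each cell's top-q transition partners; a dense -log P graph would
    make every pair adjacent and trivialize paths.
    """
    Pm = np.asarray(P.P if hasattr(P, "P") else P, dtype=float)
    n = Pm.shape[0]
    pmax = Pm.max()
    if pmax <= 0:
        raise ValueError("transition matrix has no positive entries")
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    pairs = set()
    offdiag = Pm.copy()
    np.fill_diagonal(offdiag, -np.inf)
    q = min(top_q, n - 1)
    top = np.argpartition(-offdiag, q - 1, axis=1)[:, :q]
    for i in range(n):
        for j in top[i]:
            pairs.add((i, int(j)))
    if spatial_graph is not None:
        for i, j in spatial_graph.edge_list():
            pairs.add((int(i), int(j)))
            pairs.add((int(j), int(i)))
    tiny = 1e-300
    for i, j in pairs:
        if i == j:
            continue
        p = Pm[i, j]
        if p > 0:
            G.add_edge(i, j, weight=float(-np.log(max(p, tiny) / pmax)))
    return G


def write_paths(paths: List[LineagePath], file: str) -> None:
    """Export lineage paths as JSON: one {waypoints, cost} object per path."""
    import json

    with open(file, "w") as fh:
        json.dump([{"waypoints": p.waypoints, "cost": p.cost} for p in paths],
                  fh, indent=2)


def least_action_path(P, source: int, sink: int,
                      spatial_graph=None, top_q: int = 30) -> LineagePath:
    """Minimum-cost path from source to sink on the transition graph."""
    if source == sink:
        raise ValueError("source and sink must differ")
    G = transition_graph(P, spatial_graph=spatial_graph, top_q=top_q)
    try:
        cost, path = nx.single_source_dijkstra(G, source, sink, weight="weight")
    except nx.NetworkXNoPath:
        comp = nx.node_connected_component(G.to_undirected(), sink)
        raise ValueError(
            f"sink {sink} unreachable from {source}; sink lies in a component "
            f"of {len(comp)} cells") from None
    return LineagePath(waypoints=[int(v) for v in path], cost=float(cost))


def trend_genes(ds, tau: np.ndarray, lineage: Optional[LineagePath] = None,
                n_splines: int = 6, grid_size: int = 100):
    """Score each gene by how much of its deviance a smooth of tau explains.

    Fits expression ~ s(tau) per gene with a B-spline smooth (Gaussian
    additive model, solved as ridge-stabilized penalized least squares on
    the statsmodels spline basis, which is robust to zero-residual genes),
    restricted to the lineage's cells when one is given.  Returns a
    DataFrame (gene, score) sorted by descending score and the fitted
    curves on a regular tau grid.
    """
    from statsmodels.gam.api import BSplines

    tau = np.asarray(tau, dtype=float)
    X = ds.X
    idx = np.arange(len(tau)) if lineage is None else np.asarray(lineage.waypoints)
    if idx.size < 20:
        raise ValueError(f"need >= 20 cells on the lineage, got {idx.size}")
    t = tau[idx]
    order = np.argsort(t)
    t = t[order]
    Y = np.asarray(X, dtype=float)[idx][order]
    grid = np.linspace(t.min(), t.max(), grid_size)
    bs = BSplines(t[:, None], df=[max(n_splines, 4)], degree=[3],
                  include_intercept=False)
    design = np.column_stack([np.ones(t.size), bs.basis])
    design_grid = np.column_stack([np.ones(grid_size),
                                   bs.transform(grid[:, None])])
    # ridge-stabilized normal equations shared across genes
    G = design.T @ design + 1e-8 * np.eye(design.shape[1])
    coefs = np.linalg.solve(G, design.T @ Y)        # (n_basis+1, n_genes)
    fitted = design @ coefs
    resid_dev = ((Y - fitted) ** 2).sum(axis=0)
    null_dev = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    scores = np.zeros(Y.shape[1])
    ok = null_dev > 1e-12
    scores[ok] = np.clip(1.0 - resid_dev[ok] / null_dev[ok], 0.0, 1.0)
    curves = design_grid @ coefs
    curves[:, ~ok] = Y.mean(axis=0)[~ok]
    table = pd.DataFrame({"gene": ds.gene_names, "score": scores}
                         ).sort_values("score", ascending=False,
                                       kind="stable").reset_index(drop=True)
    return table, grid, curves
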