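"""Multi-timepoint / multi-section analysis.

Strategy: separate inference per sample, joint interpretation in a shared
embedding space.  All sections are concatenated row-wise, highly variable
genes are selected batch-aware, PCA then 2-D UMAP give every cell a shared
coordinate; trajectory inference (graph -> fused cost -> OT -> pseudotime ->
velocity) then runs independently inside each section, using the shared
coordinates as the embedding-space distance so results are comparable
across sections, and per-cell velocity vectors are pooled onto one grid.
No cross-section transition probabilities are ever computed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from . import density, graph, trajectory, transport, velocity
from .datasets import SpatialDataset

log = logging.getLogger(__name__)

__all__ = ["SharedEmbedding", "SectionResult", "build_shared_embedding",
           "per_section_inference", "aggregate_fields", "global_pseudotime",
           "split_sections"]


@dataclass
class SharedEmbedding:
    umap_coords: np.ndarray         # (n_total, 2)
    pca_coords: np.ndarray          # (n_total, n_pcs)
    pca_basis: np.ndarray           # (n_hvg, n_pcs) loadings
    section_index: np.ndarray       # per-cell section label
    slices: List[np.ndarray]        # row indices of each section


@dataclass
class SectionResult:
    section: str
    transition: transport.TransitionMatrix
    pseudotime: trajectory.PseudotimeResult
    velocity: velocity.VelocityField
    shared_coords: np.ndarray


def split_sections(ds: SpatialDataset) -> List[SpatialDataset]:
    """Split one labelled dataset into per-section datasets (label order)."""
    if ds.section is None:
        return [ds]
    labels = np.asarray(ds.section).astype(str)
    return [ds.subset(np.flatnonzero(labels == s))
            for s in sorted(set(labels.tolist()))]


def build_shared_embedding(sections: Sequence[SpatialDataset],
                           n_pcs: int = 30, n_neighbors: int = 30,
                           min_dist: float = 0.3, n_hvg: int = 2000,
                           seed: int = 0) -> SharedEmbedding:
    """Concatenate sections, batch-aware HVG, PCA, then shared 2-D UMAP."""
    import scanpy as sc
    import anndata as ad
    import umap

    if len(sections) == 0:
        raise ValueError("no sections")
    genes = set(sections[0].gene_names.tolist())
    for s in sections[1:]:
        genes &= set(s.gene_names.tolist())
    full = set().union(*(set(s.gene_names.tolist()) for s in sections))
    if not genes:
        raise ValueError(
            f"disjoint gene sets across sections (intersection size 0 of {len(full)})")
    if len(genes) < len(full):
        warnings.warn(
            f"sections share only {len(genes)}/{len(full)} genes; "
            "proceeding on the intersection")
    keep = sorted(genes)
    adatas = []
    slices = []
    offset = 0
    for i, s in enumerate(sections):
        a = s.to_anndata()[:, keep].copy()
        a.obs["__section__"] = str(i)
        a.obs_names = [f"s{i}-{c}" for c in a.obs_names]
        adatas.append(a)
        slices.append(np.arange(offset, offset + s.n_cells))
        offset += s.n_cells
    adata = ad.concat(adatas, join="inner")
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    if adata.n_vars > n_hvg:
        if len(sections) > 1:
            sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg,
                                        batch_key="__section__")
        else:
            sc.pp.highly_variable_genes(adata, n_top_genes=n_hvg)
        adata = adata[:, adata.var["highly_variable"]].copy()
    n_pcs = min(n_pcs, adata.n_vars - 1, adata.n_obs - 1)
    sc.pp.pca(adata, n_comps=n_pcs, random_state=seed)
    reducer = umap.UMAP(n_neighbors=min(n_neighbors, adata.n_obs - 1),
                        min_dist=min_dist, random_state=seed)
    coords = np.asarray(reducer.fit_transform(adata.obsm["X_pca"]), dtype=float)
    section_index = np.concatenate(
        [np.full(s.n_cells, str(i)) for i, s in enumerate(sections)])
    return SharedEmbedding(
        umap_coords=coords, pca_coords=np.asarray(adata.obsm["X_pca"]),
        pca_basis=np.asarray(adata.varm["PCs"]), section_index=section_index,
        slices=slices)


def per_section_inference(shared: SharedEmbedding,
                          sections: Sequence[SpatialDataset],
                          starts: Sequence[Optional[dict]],
                          gamma: float = 0.1, d_diag: float = 1e6,
                          alpha_min: float = 0.2, alpha_max: float = 0.8,
                          graph_k: int = 6, kp: int = 15, ke: int = 15,
                          min_cells: int = 10) -> List[SectionResult]:
    """Independent trajectory inference inside each section.

    The fused cost mixes each section's own spatial distances (ds) with
    distances in the shared embedding space (dg); velocities are computed
    with displacements in shared-space coordinates.
    """
    if len(starts) != len(sections):
        raise ValueError("need one start specification per section")
    results: List[SectionResult] = []
    for i, (ds, start) in enumerate(zip(sections, starts)):
        name = (str(np.asarray(ds.section)[0]) if ds.section is not None
                else f"section_{i}")
        if ds.n_cells < min_cells:
            warnings.warn(f"section {name} has {ds.n_cells} < {min_cells} cells; skipped")
            continue
        if start is None:
            raise ValueError(f"missing start specification for section {name}")
        Zs = shared.umap_coords[shared.slices[i]]
        delta = graph.estimate_radius_delta(ds.coords, k=min(graph_k, ds.n_cells - 1))
        G = graph.build_alpha_adjacency(ds.coords, delta)
        wm = density.build_weight_map(ds.coords, G, alpha_min=alpha_min,
                                      alpha_max=alpha_max)
        fc = density.fuse_distances(Zs, ds.coords, wm.alpha_tilde)
        C = transport.build_cost_with_diagonal(fc.M, d_diag)
        P = transport.sinkhorn_transition(C, gamma=gamma)
        start_set = (start if isinstance(start, trajectory.StartSet)
                     else trajectory.select_start(ds, **start))
        pt = trajectory.pseudotime(P, start_set)
        kp_i = min(kp, ds.n_cells - 1)
        ke_i = min(ke, ds.n_cells - 1)
        nb = velocity.neighbor_union(ds.coords, Zs, kp=kp_i, ke=ke_i)
        vf = velocity.cell_velocity(nb, P, pt.tau, Zs)
        results.append(SectionResult(section=name, transition=P,
                                     pseudotime=pt, velocity=vf,
                                     shared_coords=Zs))
        log.info("section %s: n=%d sinkhorn_iters=%d", name, ds.n_cells, P.n_iter)
    return results


def aggregate_fields(results: Sequence[SectionResult],
                     b_res: int = 50, Q: float = 1.0,
                     e: float = 0.5) -> velocity.GridField:
    """Pool all per-cell vectors onto one grid over the shared space."""
    if not results:
        raise ValueError("no section results to aggregate")
    coords = np.vstack([r.shared_coords for r in results])
    v = np.vstack([r.velocity.v for r in results])
    return velocity.grid_interpolate(velocity.VelocityField(v=v), coords,
                                     b_res=b_res, Q=Q, e=e)


def global_pseudotime(results: Sequence[SectionResult]) -> np.ndarray:
    """Project per-section pseudotime onto one global axis.

    Sections are taken in the given (temporal) order; section k's cells map
    to [k, k + tau] / n_sections, so later sections are globally later.
    """
    K = len(results)
    return np.concatenate([(k + r.pseudotime.tau) / K
                           for k, r in enumerate(results)])
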