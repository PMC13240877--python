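"""Data container, file I/O and preprocessing.

The universal input object is :class:`SpatialDataset`: an expression matrix
(cells/spots x genes) plus per-cell 2-D spatial coordinates, with optional
cell-type and section/timepoint labels.  Supported on-disk layouts are an
h5ad container (coordinates in ``obsm["spatial"]``), a Matrix-Market triple
(``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` + a coordinate table)
and a pair of CSV files.  Preprocessing follows the standard single-cell
pipeline (total-count normalization, log1p, dispersion-based HVG selection,
optional scaling) via scanpy.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "SpatialDataset",
    "PreprocessConfig",
    "read_dataset",
    "write_dataset",
    "preprocess",
]


@dataclass
class SpatialDataset:
    """Expression + coordinates + labels for one tissue section.

    Parameters
    ----------
    X
        ``(n, m)`` expression matrix (counts or normalized values).
    coords
        ``(n, 2)`` spatial positions.
    gene_names, cell_ids
        Identifiers; auto-generated when omitted.
    cell_type, section
        Optional per-cell categorical labels.
    """

    X: np.ndarray
    coords: np.ndarray
    gene_names: np.ndarray = None
    cell_ids: np.ndarray = None
    cell_type: Optional[np.ndarray] = None
    section: Optional[np.ndarray] = None

    def __post_init__(self):
        if sp.issparse(self.X):
            self.X = np.asarray(self.X.todense())
        self.X = np.asarray(self.X, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("expression must be 2-D (cells x genes)")
        n, m = self.X.shape
        if n < 2:
            raise ValueError("need at least 2 cells")
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coordinates must have exactly 2 columns, got shape {self.coords.shape}; "
                "3-D coordinates are not supported"
            )
        if self.coords.shape[0] != n:
            raise ValueError(
                f"coordinate/expression mismatch ({self.coords.shape[0]} vs {n})"
            )
        if np.isnan(self.coords).any():
            raise ValueError("NaN in coordinates")
        if self.gene_names is None:
            self.gene_names = np.array([f"gene_{j}" for j in range(m)])
        else:
            self.gene_names = np.asarray(self.gene_names).astype(str)
        if self.cell_ids is None:
            self.cell_ids = np.array([f"cell_{i}" for i in range(n)])
        else:
            self.cell_ids = np.asarray(self.cell_ids).astype(str)
        for lab in ("cell_type", "section"):
            v = getattr(self, lab)
            if v is not None:
                v = np.asarray(v)
                if v.shape[0] != n:
                    raise ValueError(f"{lab} has {v.shape[0]} entries, expected {n}")
                setattr(self, lab, v)

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def copy(self) -> "SpatialDataset":
        return SpatialDataset(
            self.X.copy(), self.coords.copy(), self.gene_names.copy(),
            self.cell_ids.copy(),
            None if self.cell_type is None else np.asarray(self.cell_type).copy(),
            None if self.section is None else np.asarray(self.section).copy(),
        )

    def subset(self, idx) -> "SpatialDataset":
        idx = np.asarray(idx)
        return SpatialDataset(
            self.X[idx], self.coords[idx], self.gene_names, self.cell_ids[idx],
            None if self.cell_type is None else np.asarray(self.cell_type)[idx],
            None if self.section is None else np.asarray(self.section)[idx],
        )

    # ---- AnnData bridge -------------------------------------------------
    def to_anndata(self):
        import anndata as ad

        adata = ad.AnnData(
            X=self.X.copy(),
            obs=pd.DataFrame(index=pd.Index(self.cell_ids, name="cell_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_names, name="gene")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        if self.cell_type is not None:
            adata.obs["cell_type"] = pd.Categorical(self.cell_type)
        if self.section is not None:
            adata.obs["section"] = pd.Categorical(self.section)
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "SpatialDataset":
        if "spatial" not in adata.obsm:
            raise ValueError(
                "missing coordinates: expected a 2-column block in obsm['spatial']"
            )
        coords = np.asarray(adata.obsm["spatial"])
        X = adata.X
        if sp.issparse(X):
            X = np.asarray(X.todense())
        return cls(
            np.asarray(X, dtype=float),
            coords,
            adata.var_names.to_numpy(),
            adata.obs_names.to_numpy(),
            adata.obs["cell_type"].to_numpy() if "cell_type" in adata.obs else None,
            adata.obs["section"].to_numpy() if "section" in adata.obs else None,
        )


@dataclass
class PreprocessConfig:
    """Standard preprocessing switches.

    normalize_total: per-cell total-count normalization to ``target_sum``.
    log1p: natural-log transform of 1+x.
    n_hvg: number of highly-variable genes to retain (None disables).
    scale: unit-variance scaling per gene.
    """

    normalize_total: bool = True
    target_sum: float = 1e4
    log1p: bool = True
    n_hvg: Optional[int] = 2000
    scale: bool = False

    def __post_init__(self):
        if self.n_hvg is not None and self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1 when HVG selection is enabled")


def _read_coords_table(path: str) -> pd.DataFrame:
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    for want in ("x", "y"):
        if want not in cols:
            raise ValueError(
                f"missing coordinates: expected columns 'cell_id', 'x', 'y' in {path}"
            )
    return df


def read_dataset(path: str, fmt: str = "h5ad") -> SpatialDataset:
    """Load a :class:`SpatialDataset` from disk.

    fmt is one of ``h5ad``, ``mtx_dir`` (directory with matrix.mtx,
    barcodes.tsv, features.tsv and coords.csv/tsv), ``csv_pair``
    (``<path>.expression.csv`` + ``<path>.coords.csv``, or a directory with
    ``expression.csv`` + ``coords.csv``).  Coordinates are aligned to
    expression rows by cell identifier when present, by file order otherwise.
    """
    if fmt == "h5ad":
        import anndata as ad

        if not os.path.exists(path):
            raise FileNotFoundError(path)
        return SpatialDataset.from_anndata(ad.read_h5ad(path))

    if fmt == "mtx_dir":
        from scipy.io import mmread

        mtx = os.path.join(path, "matrix.mtx")
        bar = os.path.join(path, "barcodes.tsv")
        feat = os.path.join(path, "features.tsv")
        for f in (mtx, bar, feat):
            if not os.path.exists(f):
                raise FileNotFoundError(f)
        coords_path = None
        for cand in ("coords.csv", "coords.tsv"):
            p = os.path.join(path, cand)
            if os.path.exists(p):
                coords_path = p
                break
        if coords_path is None:
            raise ValueError(
                "missing coordinates: expected coords.csv or coords.tsv "
                "with columns (cell_id, x, y) in the mtx directory"
            )
        M = np.asarray(mmread(mtx).todense())  # genes x cells (10x layout)
        barcodes = pd.read_csv(bar, sep="\t", header=None)[0].astype(str).to_numpy()
        features = pd.read_csv(feat, sep="\t", header=None)[0].astype(str).to_numpy()
        if M.shape == (len(features), len(barcodes)):
            M = M.T
        elif M.shape != (len(barcodes), len(features)):
            raise ValueError(
                f"matrix shape {M.shape} inconsistent with "
                f"{len(barcodes)} barcodes x {len(features)} features"
            )
        cdf = _read_coords_table(coords_path)
        if len(cdf) != len(barcodes):
            raise ValueError(
                f"coordinate/expression mismatch ({len(cdf)} vs {len(barcodes)})"
            )
        if "cell_id" in {c.lower() for c in cdf.columns}:
            idcol = [c for c in cdf.columns if c.lower() == "cell_id"][0]
            cdf = cdf.set_index(cdf[idcol].astype(str))
            missing = [b for b in barcodes if b not in cdf.index]
            if missing:
                raise ValueError(
                    f"coordinate table lacks {len(missing)} barcodes (e.g. {missing[:3]})"
                )
            cdf = cdf.loc[barcodes]
        coords = cdf[[c for c in cdf.columns if c.lower() == "x"][0:1]
                     + [c for c in cdf.columns if c.lower() == "y"][0:1]].to_numpy(float)
        return SpatialDataset(M, coords, features, barcodes)

    if fmt == "csv_pair":
        if os.path.isdir(path):
            expr_path = os.path.join(path, "expression.csv")
            coords_path = os.path.join(path, "coords.csv")
        else:
            expr_path = path + ".expression.csv"
            coords_path = path + ".coords.csv"
        for f in (expr_path,):
            if not os.path.exists(f):
                raise FileNotFoundError(f)
        if not os.path.exists(coords_path):
            raise ValueError(f"missing coordinates: expected file {coords_path}")
        edf = pd.read_csv(expr_path, index_col=0)
        cdf = _read_coords_table(coords_path)
        if len(cdf) != len(edf):
            raise ValueError(
                f"coordinate/expression mismatch ({len(cdf)} vs {len(edf)})"
            )
        lower = {c.lower(): c for c in cdf.columns}
        if "cell_id" in lower:
            cdf = cdf.set_index(cdf[lower["cell_id"]].astype(str)).loc[
                edf.index.astype(str)
            ]
        coords = cdf[[lower["x"], lower["y"]]].to_numpy(float)
        return SpatialDataset(
            edf.to_numpy(float), coords, edf.columns.to_numpy(), edf.index.to_numpy()
        )

    raise ValueError(f"unknown format {fmt!r}; expected h5ad, mtx_dir or csv_pair")


def write_dataset(ds: SpatialDataset, path: str) -> None:
    """Write the dataset as an h5ad container (coords in obsm['spatial'])."""
    ds.to_anndata().write_h5ad(path)


def write_cell_table(path: str, ds: SpatialDataset, **columns) -> None:
    """Write per-cell result columns (pseudotime, weights, velocity...) to CSV."""
    df = pd.DataFrame({"x": ds.coords[:, 0], "y": ds.coords[:, 1]},
                      index=pd.Index(ds.cell_ids, name="cell_id"))
    if ds.cell_type is not None:
        df["cell_type"] = ds.cell_type
    for name, col in columns.items():
        col = np.asarray(col)
        if col.ndim == 1:
            df[name] = col
        else:
            for j in range(col.shape[1]):
                df[f"{name}_{j}"] = col[:, j]
    df.to_csv(path)


def preprocess(ds: SpatialDataset, cfg: PreprocessConfig = None) -> SpatialDataset:
    """Normalize / transform / select genes; returns a new dataset.

    Coordinates and labels pass through untouched.  HVG ranking is
    dispersion-based (seurat flavor).
    """
    import scanpy as sc

    cfg = cfg or PreprocessConfig()
    if cfg.n_hvg is not None and cfg.n_hvg > ds.n_genes:
        raise ValueError(f"n_hvg={cfg.n_hvg} exceeds gene count {ds.n_genes}")
    if cfg.normalize_total and (ds.X < 0).any():
        raise ValueError("normalize_total requires nonnegative expression")
    adata = ds.to_anndata()
    if cfg.normalize_total:
        sc.pp.normalize_total(adata, target_sum=cfg.target_sum)
    if cfg.log1p:
        sc.pp.log1p(adata)
    if cfg.n_hvg is not None and cfg.n_hvg < ds.n_genes:
        sc.pp.highly_variable_genes(adata, n_top_genes=cfg.n_hvg, flavor="seurat")
        adata = adata[:, adata.var["highly_variable"]].copy()
    if cfg.scale:
        sc.pp.scale(adata)
    out = SpatialDataset.from_anndata(adata)
    return out
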