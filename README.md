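# sptraj

Trajectory inference for spatial transcriptomics. Given a cells × genes
expression matrix and 2-D spot/cell positions, `sptraj` reconstructs the
developmental ordering of the tissue: a pseudotime per cell, a cell–cell
transition matrix, a velocity/streamline field over the tissue, and
least-action lineage paths — for developmental, regenerative, and tumor
spatial data where expression similarity alone misorders cells that are
spatially far apart.

## Method

The pipeline couples a learned representation with the raw geometry of the
tissue:

1. **Spatial graph** — the alpha-complex 1-skeleton at scale δ (Delaunay
   edges passing the Gabriel/circumradius filtration), i.e. Voronoi
   adjacency restricted to radius δ.
2. **Joint embedding** — Z = [Zf ‖ Zg]: a masked two-layer MLP encodes
   expression into Zf; a variational graph convolutional encoder on the
   spatial graph yields Zg. Two-stage training: reconstruction + VGAE +
   masked-token losses, then a DEC-style clustering fine-tune.
3. **Density-adaptive fusion** — per-cell Gaussian-KDE density ρ_i maps to
   a spatial weight α_i = αmin + (1−ρ_i)(αmax−αmin); low-confidence cells
   (tissue edge, holes, poor connectivity) get a fixed neutral weight. The
   transport cost is M_ij = α̃_i·ds(i,j) + (1−α̃_i)·dg(i,j) over
   max-normalized spatial (ds) and embedding (dg) distances.
4. **Entropic optimal transport** — P = argmin ⟨P,M⟩_F + γ Σ P log P with
   uniform marginals (γ = 0.1), diagonal of M raised to 1e6 to forbid
   self-transitions, solved by log-domain Sinkhorn.
5. **Pseudotime** — accumulated probability from a user-specified start
   set, O_i = Σ_{j∈S} P_ji, rank-normalized to τ ∈ [0,1] and oriented so
   the start set sits at τ ≈ 0.
6. **Velocity** — probability-weighted displacement directions over the
   union of spatial and embedding neighborhoods, signed by the pseudotime
   gradient, kernel-interpolated onto a grid and integrated into
   streamlines.

A synthetic generator provides branching trajectories (bifurcating,
trifurcating with linear or curved spatial layouts, independent dual
paths, multi-section time series) with ground-truth time, branch, and
direction for validation. See `docs/methods.md` for the full model.

## Worked example

Simulate a bifurcating tissue and run the pipeline from the shell:

```bash
sptraj simulate --topology bifurcating --n-cells 500 --seed 1 --out sim.h5ad
sptraj run --input sim.h5ad --start-type root --seed 1 --out results/
```

which prints

```
wrote sim.h5ad (500 cells x 200 genes)
wrote results/cells.csv  (n=500, hash=0991d8d0c214bbf9)
```

`results/cells.csv` holds one row per cell: position, pseudotime `tau`
(0 = the "root"-labelled start cells, 1 = the most terminal cell), the
density-adaptive spatial weight `alpha_tilde`, the low-confidence flag,
and the velocity vector. Comparing against the generator's truth:

```python
import pandas as pd
from scipy.stats import spearmanr
cells = pd.read_csv("results/cells.csv")
truth = pd.read_csv("sim.truth.csv")
print(spearmanr(cells["tau"], truth["true_time"]).statistic)
# 0.964  — inferred pseudotime reproduces the true developmental order
```

The same analysis from Python (`sptraj.run_pipeline`) returns the full
bundle: the embedding, transition matrix, pseudotime, velocity field and
grid; `sptraj.trajectory.least_action_path` extracts lineage paths and
`sptraj.trajectory.trend_genes` ranks pseudotime-dependent genes.

Multi-section time series go through `sptraj multirun` (or
`sptraj.multisection`): sections are embedded into one shared UMAP space,
inference runs independently per section, and velocities are pooled onto a
single grid — no cross-section transition probabilities are computed.

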