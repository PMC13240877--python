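# Methods

`sptraj` infers developmental trajectories from spatial transcriptomics:
given an expression matrix X (n cells/spots × m genes) and 2-D positions
s_i, it produces a pseudotime τ per cell, a cell–cell transition matrix, a
velocity/streamline field, and least-action lineage paths. This note
documents the model, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and known limitations.

## Pipeline

**Spatial graph.** Cells are connected by the 1-skeleton of the alpha
complex at scale δ: a Delaunay edge is kept iff its filtration radius
(half-length when the diametral disk is empty of other sites — the Gabriel
case — otherwise the smallest circumradius of an incident triangle) is at
most δ. This equals the radius-restricted Voronoi adjacency: two cells are
linked iff their shared Voronoi facet comes within δ of both sites. δ
defaults to the mean k-NN distance over all cells with k = 6 (a typical
spot-neighborhood size on hexagonal arrays). Collinear or duplicated
geometry falls back to a symmetric 6-NN graph with a warning. Adjacency is
stored sparsely.

**Joint embedding Z = [Zf ‖ Zg].** A masked two-layer ReLU MLP maps X
(with a random 20% of rows replaced by learnable token vectors during
training) to a nonnegative feature embedding Zf (hf = 32 ≪ m). A two-layer
variational GCN on the symmetric-normalized graph operator
D̃^{−1/2}(A+I)D̃^{−1/2} maps Zf to a per-cell Gaussian posterior (μ, log σ);
Zg is the reparameterized sample during training and μ at inference.
Training is full-batch Adam (lr 1e-3), seed 2025 by default, in two stages:

* *Pretraining* (200 epochs): λrec·Lrec + λgcn·Lgcn + λself·Lself with
  λrec = 10, λgcn = 0.1, λself = 1. Lrec is the MSE of a two-layer decoder
  reconstructing X from Z; Lgcn is the VGAE objective (positively-weighted
  BCE between σ(Zg Zgᵀ) and the self-looped adjacency, plus the KL of the
  posterior to N(0, I)); Lself is the masked-row loss ‖x_i − x̃_i‖² pulling
  each token toward the row it replaces.
* *Fine-tuning* (200 epochs): the mask objective is removed (the input is
  the unmasked matrix), and a DEC-style clustering loss (KL between
  Student-t soft assignments to K-means-initialized centers, k = 5 by
  default, and their sharpened targets, refreshed each epoch with stopped
  gradient) is added with λcluster = 1.

The implementation is plain numpy with analytically derived gradients; a
finite-difference check in the test suite covers every parameter block of
both stages. Determinism is exact for a fixed seed on a given BLAS.

**Density-adaptive fusion.** Per-cell density is
ρ̂_i = exp((1/(n·b)) Σ_j K(‖s_i−s_j‖/b)) with the standard Gaussian kernel
and bandwidth b; ρ̂ is min-max normalized (ε = 1e-10) to ρ ∈ [0,1]. The
spatial weight is the affine reverse map α_i = αmin + (1−ρ_i)(αmax−αmin)
with (αmin, αmax) = (0.2, 0.8) by default: dense regions trust the
embedding, sparse regions trust raw spatial proximity. b defaults to
Scott's rule (n^{−1/6} × mean coordinate std) so the field reflects
regional crowding rather than nearest-neighbor sampling noise. Cells whose
local geometry is unreliable — convex-hull (tissue-edge) cells, cells whose
mean neighbor distance exceeds 3× the median edge length (hole-adjacent),
or cells with graph degree < 2 — are *protected*: they receive the fixed
neutral weight αprot = (αmin+αmax)/2, since low confidence means the
density estimate itself is untrustworthy and neither extreme is justified.
The fused cost is M_ij = α̃_i·ds(i,j) + (1−α̃_i)·dg(i,j) on max-normalized
spatial (ds) and embedding (dg) distances; M is left asymmetric because α̃
indexes the source cell. The weight range is deliberately dataset-specific:
(0.2, 0.8) is a balanced default suited to data whose expression signal is
strong; sparse or noisy-expression tissues can warrant a high-spatial
range such as (0.7, 1.0). Both bounds, the bandwidth, αprot and the
protection thresholds are exposed in configuration.

**Entropic optimal transport.** The transition structure is
P = argmin ⟨P, M⟩_F + γ Σ P log P subject to uniform marginals
P1 = Pᵀ1 = (1/n)1, with γ = 0.1. The diagonal of M is set to d_diag = 1e6
before solving, which suppresses self-transitions (max_i P_ii < 1e-8); the
plan is insensitive to the exact constant across 1e5–1e9. The solver is
log-domain Sinkhorn (mandatory: exp(−1e7) underflows naive scaling),
tolerance 1e-9 on the marginal violation, max 10 000 iterations,
convergence checked every 10. The raw plan sums to 1; consumers that need
per-cell transition probabilities row-normalize it.

**Pseudotime.** Start cells come from prior knowledge: all cells of a
named type, or the k nearest to a known morphogenesis center (ties broken
by lowest index). Accumulated probability O_i = Σ_{j∈S} P_ji is ranked
ascending (stable index tie-break) and normalized, τ = rank/(N−1), so τ is
a bijection onto {0, 1/(N−1), …, 1}. Because accumulated mass is largest
*near* the start set while τ ≈ 0 must mark the initial state, the default
orientation flips τ → 1−τ whenever the start cells' mean τ exceeds 0.5;
the raw ascending convention is available behind a flag.

**Lineage paths and trend genes.** Least-action paths are Dijkstra
shortest paths under edge cost −log(P_ij / max P), restricted to the union
of spatial-graph edges and each cell's top-30 transition partners (a dense
−log P graph would make every pair adjacent and trivialize paths). Genes
varying along a lineage are scored by a B-spline smooth of expression
against τ (6 basis functions, Gaussian model fitted by ridge-stabilized
penalized least squares — equivalent to the Gaussian additive-model fit
and robust to zero-residual genes); the score is deviance explained.

**Velocity field.** Each cell's neighborhood N_i is the union of its
spatial 15-NN and embedding 15-NN. The velocity is
v_i = (1/|N_i|) Σ_{j∈N_i} γ_ij (s_j−s_i)/(‖s_j−s_i‖+1e-10), with
γ_ij = +p_ij toward later-pseudotime neighbors and −p_ij toward earlier
(ties use +), and p_ij the plan row-normalized over N_i. Flipping τ → 1−τ
negates every v_i exactly (a test asserts this bitwise). Velocities are
interpolated onto a ⌊b·Q⌋×⌊b·Q⌋ grid (b = 50, Q = 1.0) with a Gaussian
kernel of bandwidth σ = ((Xmax−Xmin)+(Ymax−Ymin))/2 × 1/(⌊bQ⌋−1) × e
(e = 0.5); the denominator max(1, Σφ) damps the far field instead of
renormalizing it. Streamlines integrate the bilinear grid field with RK4
(step = half the grid spacing, max 500 steps, seeds on every 2nd node,
stopping below 1e-3 of the peak speed or outside the box).

**Multi-section data.** Sections are analyzed under "separate inference
per sample, joint interpretation in a shared space": all sections are
concatenated, HVGs selected batch-aware, PCA (30 components) then 2-D UMAP
(30 neighbors, min_dist 0.3) give every cell a shared coordinate. Within
each section the pipeline runs independently, with dg taken from the
shared coordinates (so pseudotimes and velocities are comparable across
sections) and ds from the section's own coordinates; no cross-section
transition probabilities are ever computed. Per-cell velocities are pooled
onto one grid over the shared space, and a global projected pseudotime
maps section k's cells to [k, k+τ]/K using the user-supplied temporal
order. Sections with fewer than 10 cells are skipped with a warning.

**Ablation switches** (for component attribution): `no_spatial_reuse`
drops the explicit ds term (M = dg); `no_adaptive_density` freezes
α̃ ≡ (αmin+αmax)/2; `no_embedding` replaces Z by PCA of the preprocessed
expression; `no_cluster_loss` skips the fine-tuning stage;
`no_fusion_module` removes the fusion entirely (M = dg, density never
estimated).

## Synthetic data generator

Each cell draws a latent time t ~ U(0,1) and a branch; topologies are a
single path, a bifurcation or trifurcation (branches emerge at t = 0.35,
so later branches have time support [0.35, 1] and lineage time
distributions genuinely differ), and two independent paths. Expression is
built from smooth programs of t: per-branch sigmoid markers (8 per
branch), early "trunk" programs that decay, shared temporal programs, and
constant housekeeping genes, with Poisson-lognormal count noise (log-sd
0.6) at shallow depth. Program onsets are Beta(1.2, 2)-distributed over
the process — early-biased, as differentiation dynamics typically are, but
with full support so no time window is expression-dead. Spatial maps
place cells along branch-specific rays (linear), curved arcs (nonlinear),
or radially outward, on a length-10 path with Gaussian jitter (sd 1.2).
Multi-section configurations assign cells to sections by sampling time
t + N(0, 0.15) — developmental asynchrony, so each section contains a
spread of true stages — and give each section its own centered coordinate
frame and its own "root" labels on its earliest cells. The generator also
emits a lagged unspliced/spliced count pair for format completeness; the
pipeline does not use it.

Noise levels were calibrated once so that full-model recovery lands in a
realistic ~0.9–0.97 Spearman band rather than saturating at 1, and then
frozen. What the generator does **not** emulate:
kinetic transcription bursting, spatial covariance of technical noise,
segmentation artifacts, doublets, batch effects beyond section frames, or
cell-cell communication. Passing recovery tests therefore demonstrates
correctness of the machinery on idealized branching processes, not
performance on any real tissue.

## Numerical choices and degenerate inputs

Log-domain Sinkhorn throughout; logσ clipped to ±10 during training;
ridge 1e-8 in the spline normal equations; ε = 1e-10 in density
normalization and velocity denominators; max-normalized distances raise an
error when all coordinates coincide; constant accumulated-probability
fields warn and rank by index; duplicated coordinates warn in δ
estimation; an all-zero velocity field yields no streamlines.

## Known limitations

Dense n×n matrices bound practical size to a few thousand cells per
section. The encoder is CPU-scale by design. Branch-point detection and
automatic lineage-tree construction are out of scope (endpoints come from
prior knowledge), as are 3-D coordinates, cross-slice alignment and
splicing-based velocity. The adaptive-density component's advantage over a
constant weight is modest on the synthetic designs; it is motivated
primarily by robustness on heterogeneous real tissue.

## Problem sizes used in tests and the acceptance script

Simulation-scale checks run the five designs at n = 500 cells × 200 genes
(5 seeds in the test suite; 3-seed medians in the acceptance script), the
transport checks at n = 200, the multi-section scenario at 600 cells over
4 sections, and unit-scale oracles at n ≤ 50.
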