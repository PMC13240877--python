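"""Synthetic spatial-trajectory datasets with ground truth.

The generator emulates branching developmental processes laid out in a
tissue: each cell has a latent time t in [0,1] and a branch; expression is
built from smooth gene programs of t (sequentially activating sigmoid
markers per branch, early "trunk" programs that decay, shared temporal
programs, constant housekeeping genes) with Poisson-lognormal count noise;
spatial position applies a branch-specific map to (t, branch) plus Gaussian
jitter.  Five designs are covered: a bifurcation, a trifurcation with a
linear or a curved (nonlinear) spatial layout, two independent paths, and a
multi-section/multi-timepoint scenario in which consecutive time windows
live on separate coordinate frames.  Later-emerging branches have time
support [branch_time, 1], so lineage time distributions genuinely differ.

Every dataset carries true_time, true_branch, a two-way true_lineage label
and the true local direction of motion, which downstream tests use as
recovery oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpatialDataset

__all__ = ["SimConfig", "SimResult", "simulate", "evaluate_pseudotime"]


@dataclass
class SimConfig:
    topology: str = "bifurcating"       # linear | bifurcating | trifurcating | dual_path
    spatial_pattern: str = "linear_map"  # linear_map | nonlinear_map | radial
    n_cells: int = 500
    n_genes: int = 200
    n_marker_genes_per_branch: int = 8
    noise_sd: float = 0.6
    n_sections: int = 1
    seed: int = 0
    branch_time: float = 0.35           # when branches emerge
    path_length: float = 10.0
    coord_noise: float = 1.2            # jitter sd, absolute units
    root_fraction: float = 0.08         # earliest cells labelled "root"
    section_async: float = 0.15         # developmental asynchrony of sections

    def __post_init__(self):
        if self.n_cells < 50:
            raise ValueError("n_cells must be >= 50")
        branches = _branch_names(self.topology)
        need = self.n_marker_genes_per_branch * len(branches)
        if self.n_genes < need:
            raise ValueError(
                f"n_genes={self.n_genes} too small for "
                f"{len(branches)} branch programs of {self.n_marker_genes_per_branch}")


@dataclass
class SimResult:
    dataset: SpatialDataset
    true_time: np.ndarray
    true_branch: np.ndarray
    true_lineage: np.ndarray
    true_direction: np.ndarray
    spliced: np.ndarray = None
    unspliced: np.ndarray = None


def _branch_names(topology: str):
    return {
        "linear": ["trunk", "A"],
        "bifurcating": ["trunk", "A", "B"],
        "trifurcating": ["trunk", "A", "B", "C"],
        "dual_path": ["P1", "P2"],
    }[topology]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _branch_geometry(topology: str):
    """Unit direction of the trunk and of each terminal branch."""
    if topology == "dual_path":
        return {"P1": 0.0, "P2": np.pi}      # opposite rays from distinct origins
    angles = {"trunk": 0.0}
    fan = {"bifurcating": [-0.7, 0.7], "trifurcating": [-0.9, 0.0, 0.9],
           "linear": [0.0]}[topology]
    for name, a in zip("ABC", fan):
        angles[name] = a
    return angles


def _positions(t, branch, cfg: SimConfig, rng):
    """Noise-free position and unit tangent for each cell."""
    L, t0 = cfg.path_length, cfg.branch_time
    n = t.size
    pos = np.zeros((n, 2))
    tangent = np.zeros((n, 2))
    angles = _branch_geometry(cfg.topology)

    if cfg.spatial_pattern == "radial":
        # outward from a common origin; each branch owns an angular sector
        names = [b for b in _branch_names(cfg.topology) if b != "trunk"]
        width = 2.0 * np.pi / len(names)
        base = {b: i * width for i, b in enumerate(names)}
        theta = np.zeros(n)
        for i in range(n):
            b = branch[i] if branch[i] in base else None
            if b is None:            # trunk cells: sector of their future? use hash
                b = names[i % len(names)]
            theta[i] = base[b] + rng.uniform(0.05, 0.95) * width
        r = np.maximum(t, 1e-3) * L
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        tangent = np.column_stack([np.cos(theta), np.sin(theta)])
        return pos, tangent

    if cfg.topology == "dual_path":
        origins = {"P1": np.array([0.0, 0.0]), "P2": np.array([0.0, 4.0])}
        for i in range(n):
            a = angles[branch[i]]
            u = np.array([np.cos(a), np.sin(a)])
            if cfg.spatial_pattern == "nonlinear_map":
                kappa = 1.2
                th = a + kappa * t[i]
                pos[i] = origins[branch[i]] + (L / kappa) * np.array(
                    [np.sin(th) - np.sin(a), -np.cos(th) + np.cos(a)])
                tangent[i] = [np.cos(th), np.sin(th)]
            else:
                pos[i] = origins[branch[i]] + t[i] * L * u
                tangent[i] = u
        return pos, tangent

    bp = np.array([t0 * L, 0.0])            # branch point at end of trunk
    for i in range(n):
        if t[i] < t0 or branch[i] == "trunk":
            pos[i] = [t[i] * L, 0.0]
            tangent[i] = [1.0, 0.0]
            continue
        a = angles[branch[i]]
        dt = t[i] - t0
        if cfg.spatial_pattern == "nonlinear_map":
            kappa = 1.8
            th = a + kappa * dt
            pos[i] = bp + (L / kappa) * np.array(
                [np.sin(th) - np.sin(a), -np.cos(th) + np.cos(a)])
            tangent[i] = [np.cos(th), np.sin(th)]
        else:
            u = np.array([np.cos(a), np.sin(a)])
            pos[i] = bp + dt * L * u
            tangent[i] = u
    return pos, tangent


def _gene_programs(cfg: SimConfig, rng):
    """Per-gene (kind, branch, onset, amplitude, sign) tables."""
    branches = _branch_names(cfg.topology)
    kinds, owner, onset, amp, sign = [], [], [], [], []
    t0 = cfg.branch_time
    # program onsets are early-biased (Beta-distributed) but span the whole
    # process: differentiation dynamics are densest early yet late
    # maturation programs still exist, so no time window is expression-dead
    for b in branches:
        lo, hi = ((0.0, t0) if b == "trunk" else
                  (0.05, 0.95) if cfg.topology == "dual_path" else (t0, 0.95))
        for _ in range(cfg.n_marker_genes_per_branch):
            kinds.append("marker")
            owner.append(b)
            onset.append(lo + (hi - lo) * rng.beta(1.2, 2.0))
            amp.append(rng.uniform(1.0, 3.0))
            sign.append(1.0)
    n_left = cfg.n_genes - len(kinds)
    n_shared = n_left // 2
    for _ in range(n_shared):
        kinds.append("shared")
        owner.append(None)
        onset.append(0.05 + 0.9 * rng.beta(1.2, 2.0))
        amp.append(rng.uniform(1.0, 3.0))
        sign.append(rng.choice([-1.0, 1.0]))
    for _ in range(n_left - n_shared):
        kinds.append("housekeeping")
        owner.append(None)
        onset.append(0.0)
        amp.append(rng.uniform(0.5, 1.5))
        sign.append(1.0)
    return kinds, owner, onset, np.array(amp), np.array(sign)


def _mean_expression(t, branch, cfg: SimConfig, programs):
    kinds, owner, onset, amp, sign = programs
    n = t.size
    mean = np.full((n, cfg.n_genes), 0.05)
    steep = 1.0 / 0.07
    for j in range(cfg.n_genes):
        if kinds[j] == "marker":
            b = owner[j]
            act = _sigmoid((t - onset[j]) * steep)
            if b == "trunk":
                # early program: on everywhere, decaying with time
                mean[:, j] += amp[j] * (1.0 - act)
            else:
                on_branch = branch == b
                mean[on_branch, j] += amp[j] * act[on_branch]
        elif kinds[j] == "shared":
            act = _sigmoid((t - onset[j]) * steep * 0.8)
            prog = act if sign[j] > 0 else 1.0 - act
            mean[:, j] += amp[j] * prog
    hk = [j for j in range(cfg.n_genes) if kinds[j] == "housekeeping"]
    mean[:, hk] += amp[hk]
    return mean


def _counts(mean, cfg: SimConfig, rng):
    # Poisson-lognormal: overdispersed counts at modest sequencing depth
    logn = rng.normal(0.0, cfg.noise_sd, size=mean.shape)
    lam = 1.5 * mean * np.exp(logn)
    return rng.poisson(lam).astype(float)


def simulate(cfg: SimConfig) -> SimResult:
    """Draw one synthetic dataset under ``cfg`` (fully seeded)."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cells
    branches = _branch_names(cfg.topology)
    t = rng.uniform(0.0, 1.0, size=n)
    if cfg.topology == "dual_path":
        branch = rng.choice(["P1", "P2"], size=n)
    else:
        terminal = [b for b in branches if b != "trunk"]
        branch = np.where(
            t < cfg.branch_time, "trunk", rng.choice(terminal, size=n))
        branch = branch.astype(object).astype(str)
    # two-way lineage label: first terminal branch (plus trunk) vs the rest
    if cfg.topology == "dual_path":
        lineage = np.where(branch == "P1", "L1", "L2")
    else:
        first = [b for b in branches if b != "trunk"][0]
        lineage = np.where((branch == "trunk") | (branch == first), "L1", "L2")

    programs = _gene_programs(cfg, rng)
    mean = _mean_expression(t, branch, cfg, programs)
    X = _counts(mean, cfg, rng)
    mean_unspliced = _mean_expression(np.clip(t + 0.05, 0, 1), branch, cfg, programs)
    U = _counts(mean_unspliced, cfg, rng)

    pos, tangent = _positions(t, branch, cfg, rng)
    pos = pos + rng.normal(0.0, cfg.coord_noise, size=pos.shape)
    if cfg.spatial_pattern == "radial":
        # the outward field direction is a property of where the cell sits:
        # evaluate it at the observed (jittered) position
        norm = np.linalg.norm(pos, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        tangent = pos / norm

    section = None
    cell_type = np.asarray(branch, dtype=object)
    if cfg.n_sections > 1:
        # sampling-time assignment with developmental asynchrony: a section
        # collects cells around a stage window, not a sharp quantile cut
        t_sample = t + rng.normal(0.0, cfg.section_async, size=n)
        edges = np.quantile(t_sample, np.linspace(0, 1, cfg.n_sections + 1))
        sec_idx = np.clip(np.searchsorted(edges[1:-1], t_sample, side="right"),
                          0, cfg.n_sections - 1)
        section = np.array([f"T{s + 1}" for s in sec_idx])
        # each section is its own slide: recenter per section
        for s in range(cfg.n_sections):
            m = sec_idx == s
            pos[m] -= pos[m].mean(axis=0)
        # per-section prior-knowledge root labels (earliest cells per slide)
        for s in range(cfg.n_sections):
            m = np.flatnonzero(sec_idx == s)
            cut = np.quantile(t[m], cfg.root_fraction)
            cell_type[m[t[m] <= cut]] = "root"
    else:
        cell_type[t < cfg.root_fraction] = "root"

    ds = SpatialDataset(
        X=X, coords=pos,
        gene_names=np.array([f"g{j:04d}" for j in range(cfg.n_genes)]),
        cell_ids=np.array([f"c{i:05d}" for i in range(n)]),
        cell_type=cell_type.astype(str),
        section=section,
    )
    return SimResult(dataset=ds, true_time=t, true_branch=np.asarray(branch),
                     true_lineage=lineage, true_direction=tangent,
                     spliced=X, unspliced=U)


def evaluate_pseudotime(tau: np.ndarray, truth: np.ndarray):
    """(Spearman, Kendall) rank agreement between pseudotime and true time."""
    import warnings

    from scipy.stats import kendalltau, spearmanr

    tau = np.asarray(tau, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if tau.shape != truth.shape:
        raise ValueError("length mismatch")
    if np.allclose(tau, tau[0]) or np.allclose(truth, truth[0]):
        warnings.warn("constant input: correlation undefined, returning NaN")
        return float("nan"), float("nan")
    s = spearmanr(tau, truth).statistic
    k = kendalltau(tau, truth).statistic
    return float(s), float(k)
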