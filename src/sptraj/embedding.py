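"""Joint gene + space embedding Z = [Zf || Zg].

Two encoders share one latent representation: a two-layer ReLU MLP maps the
(row-masked) expression matrix to a nonnegative feature embedding Zf, and a
two-layer variational graph convolutional encoder on the spatial graph maps
Zf to a Gaussian posterior (mu, log_sigma) whose sample (or mean, at
inference) is the graph embedding Zg.  Training is full-batch Adam in two
stages:

* pretraining minimizes  lambda_rec * L_rec + lambda_gcn * L_gcn +
  lambda_self * L_self,  where L_rec is the MSE of a symmetric two-layer
  decoder reconstructing the expression matrix from Z, L_gcn the standard
  VGAE objective (weighted BCE on adjacency reconstruction by inner-product
  decoder, plus the KL to the standard normal prior), and L_self the
  masked-row reconstruction pulling the learnable mask tokens toward the
  rows they replace;
* fine-tuning drops L_self and adds a DEC-style clustering loss (KL between
  Student-t soft assignments to K-means-initialized centers and their
  sharpened targets).

Everything is plain numpy with analytically derived gradients; determinism
is controlled by a single seed (default 2025).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .graph import SpatialGraph

__all__ = [
    "MaskSpec",
    "EncoderConfig",
    "LossWeights",
    "JointEmbedding",
    "mask_expression",
    "encode_features",
    "encode_graph_vgae",
    "pretrain",
    "finetune_with_clustering",
    "fit_embedding",
    "pca_embedding",
]


# --------------------------------------------------------------------------
# configuration containers
# --------------------------------------------------------------------------

@dataclass
class MaskSpec:
    mask_set: np.ndarray          # index subset U
    mask_fraction: float
    tokens: Optional[np.ndarray] = None   # learnable per-node vectors x~_i


@dataclass
class EncoderConfig:
    h: int = 64                   # hidden width of both MLPs
    hf: int = 32                  # feature-embedding dim (must be < n_genes)
    hg: int = 32                  # graph-embedding dim
    seed: int = 2025
    epochs_pretrain: int = 200
    epochs_finetune: int = 200
    lr: float = 1e-3
    n_clusters: int = 5
    mask_fraction: float = 0.2


@dataclass
class LossWeights:
    lambda_rec: float = 10.0
    lambda_gcn: float = 0.1
    lambda_self: float = 1.0
    lambda_cluster: float = 1.0

    def __post_init__(self):
        for name in ("lambda_rec", "lambda_gcn", "lambda_self", "lambda_cluster"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class JointEmbedding:
    Zf: np.ndarray
    Zg: np.ndarray
    Z: np.ndarray
    mu: np.ndarray
    log_sigma: np.ndarray
    losses: List[Dict[str, float]] = field(default_factory=list)
    params: Optional[Dict[str, np.ndarray]] = None
    config: Optional[EncoderConfig] = None


# --------------------------------------------------------------------------
# masking
# --------------------------------------------------------------------------

def mask_expression(X: np.ndarray, mask_fraction: float, rng_seed: int,
                    tokens: Optional[np.ndarray] = None):
    """Replace a random row subset U by learnable token vectors.

    Returns (X', MaskSpec).  |U| = round(mask_fraction * n); tokens are
    initialized small-random when not supplied.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if not (0 < mask_fraction < 1):
        raise ValueError("mask_fraction must lie in (0, 1)")
    n_mask = int(round(mask_fraction * n))
    if n_mask == 0 or n_mask == n:
        raise ValueError(f"mask_fraction={mask_fraction} masks {n_mask} of {n} rows")
    rng = np.random.default_rng(rng_seed)
    U = np.sort(rng.choice(n, size=n_mask, replace=False))
    if tokens is None:
        tokens = 0.01 * rng.standard_normal((n, m))
    Xp = X.copy()
    Xp[U] = tokens[U]
    return Xp, MaskSpec(mask_set=U, mask_fraction=mask_fraction, tokens=tokens)


# --------------------------------------------------------------------------
# parameter handling
# --------------------------------------------------------------------------

def _glorot(rng, shape):
    lim = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-lim, lim, size=shape)


def init_params(n: int, m: int, cfg: EncoderConfig) -> Dict[str, np.ndarray]:
    if cfg.hf >= m:
        raise ValueError(f"hf={cfg.hf} must be smaller than the gene dimension m={m}")
    rng = np.random.default_rng(cfg.seed)
    h, hf, hg = cfg.h, cfg.hf, cfg.hg
    d = hf + hg
    return {
        "T": 0.01 * rng.standard_normal((n, m)),       # mask tokens
        "W1": _glorot(rng, (m, h)), "b1": np.zeros(h),
        "W2": _glorot(rng, (h, hf)), "b2": np.zeros(hf),
        "W0": _glorot(rng, (hf, hg)),
        "Wmu": _glorot(rng, (hg, hg)),
        "Wsg": _glorot(rng, (hg, hg)),
        "V1": _glorot(rng, (d, h)), "c1": np.zeros(h),
        "V2": _glorot(rng, (h, m)), "c2": np.zeros(m),
    }


def normalized_propagation(adjacency: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric-normalized propagation operator D~^{-1/2} (A+I) D~^{-1/2}."""
    n = adjacency.shape[0]
    At = adjacency + sp.eye(n, format="csr")
    deg = np.asarray(At.sum(axis=1)).ravel()
    dinv = 1.0 / np.sqrt(deg)
    D = sp.diags(dinv)
    return (D @ At @ D).tocsr()


# --------------------------------------------------------------------------
# forward passes (functional, reused by training and inference)
# --------------------------------------------------------------------------

def encode_features(Xp: np.ndarray, params: Dict[str, np.ndarray]) -> np.ndarray:
    """Zf = ReLU(ReLU(X' W1 + b1) W2 + b2); nonnegative by construction."""
    if not np.isfinite(Xp).all():
        raise ValueError("non-finite values in encoder input")
    H1 = np.maximum(Xp @ params["W1"] + params["b1"], 0.0)
    return np.maximum(H1 @ params["W2"] + params["b2"], 0.0)


def encode_graph_vgae(Zf: np.ndarray, graph: SpatialGraph,
                      params: Dict[str, np.ndarray], sample: bool = False,
                      eps: Optional[np.ndarray] = None,
                      S: Optional[sp.spmatrix] = None):
    """Two-layer GCN posterior heads; returns (mu, log_sigma, Zg).

    ``sample=False`` gives inference mode (Zg = mu); with ``sample=True``
    the reparameterized draw Zg = mu + eps * exp(log_sigma) is returned.
    """
    if S is None:
        S = normalized_propagation(graph.adjacency)
    P1 = S @ Zf
    Hg = np.maximum(P1 @ params["W0"], 0.0)
    P2 = S @ Hg
    mu = P2 @ params["Wmu"]
    ls = P2 @ params["Wsg"]
    if not (np.isfinite(mu).all() and np.isfinite(ls).all()):
        raise ValueError("NaN/inf in graph propagation")
    if sample:
        if eps is None:
            eps = np.random.default_rng(0).standard_normal(mu.shape)
        Zg = mu + eps * np.exp(ls)
    else:
        Zg = mu
    return mu, ls, Zg


# --------------------------------------------------------------------------
# loss + analytic gradients (single fused pass)
# --------------------------------------------------------------------------

def _softplus_pair(x):
    """(softplus(x), softplus(-x)) from one exp/log1p pass."""
    sp = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)
    return sp, sp - x


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _student_q(Z, C):
    d2 = ((Z[:, None, :] - C[None, :, :]) ** 2).sum(-1)
    w = 1.0 / (1.0 + d2)
    return w / w.sum(axis=1, keepdims=True), w


def dec_target(q: np.ndarray) -> np.ndarray:
    """Sharpened auxiliary distribution p = (q^2/f) row-normalized."""
    f = q.sum(axis=0)
    p = q ** 2 / f
    return p / p.sum(axis=1, keepdims=True)


def loss_and_grads(params, X, mask_set, S, At, pos_weight, weights: LossWeights,
                   eps, stage: str, cluster_p=None, centers=None,
                   use_mask=True, sample=True):
    """One fused forward/backward pass.

    Returns (loss_terms: dict, grads: dict).  ``stage`` is "pretrain"
    (rec + gcn + self) or "finetune" (rec + gcn + cluster, centers trained).
    """
    n, m = X.shape
    hf = params["W2"].shape[1]
    U = mask_set if use_mask else np.array([], dtype=int)

    Xp = X.copy()
    if U.size:
        Xp[U] = params["T"][U]
    A1 = Xp @ params["W1"] + params["b1"]
    H1 = np.maximum(A1, 0.0)
    A2 = H1 @ params["W2"] + params["b2"]
    Zf = np.maximum(A2, 0.0)
    P1 = S @ Zf
    B0 = P1 @ params["W0"]
    Hg = np.maximum(B0, 0.0)
    P2 = S @ Hg
    mu = P2 @ params["Wmu"]
    ls = np.clip(P2 @ params["Wsg"], -10.0, 10.0)
    sg = np.exp(ls)
    Zg = mu + eps * sg if sample else mu
    Z = np.concatenate([Zf, Zg], axis=1)
    D0 = Z @ params["V1"] + params["c1"]
    D1 = np.maximum(D0, 0.0)
    Xh = D1 @ params["V2"] + params["c2"]

    terms = {}
    # reconstruction of the (unmasked) expression matrix
    R = Xh - X
    terms["rec"] = float((R ** 2).mean())
    # VGAE: weighted BCE on inner-product adjacency logits + KL
    logits = Zg @ Zg.T
    sp_pos, sp_neg = _softplus_pair(logits)
    bce = pos_weight * At * sp_neg + (1.0 - At) * sp_pos
    terms["gcn_bce"] = float(bce.mean())
    terms["gcn_kl"] = float(0.5 / n * (mu ** 2 + sg ** 2 - 1.0 - 2.0 * ls).sum())
    terms["gcn"] = terms["gcn_bce"] + terms["gcn_kl"]
    if stage == "pretrain" and U.size:
        dT_self = params["T"][U] - X[U]
        terms["self"] = float((dT_self ** 2).sum() / U.size)
    else:
        dT_self = None
        terms["self"] = 0.0
    if stage == "finetune":
        q, w = _student_q(Z, centers)
        # stop-gradient sharpened target, refreshed from the current q
        p = dec_target(q) if cluster_p is None else cluster_p
        terms["cluster"] = float((p * (np.log(p + 1e-12) - np.log(q + 1e-12))).sum() / n)
    else:
        terms["cluster"] = 0.0
    terms["total"] = (weights.lambda_rec * terms["rec"]
                      + weights.lambda_gcn * terms["gcn"]
                      + weights.lambda_self * terms["self"]
                      + weights.lambda_cluster * terms["cluster"])

    # ---- backward ------------------------------------------------------
    g = {k: np.zeros_like(v) for k, v in params.items()}

    dXh = weights.lambda_rec * 2.0 / (n * m) * R
    g["V2"] = D1.T @ dXh
    g["c2"] = dXh.sum(0)
    dD0 = (dXh @ params["V2"].T) * (D0 > 0)
    g["V1"] = Z.T @ dD0
    g["c1"] = dD0.sum(0)
    dZ = dD0 @ params["V1"].T

    if stage == "finetune":
        # DEC gradient: dL/dz_i = (2/n) sum_k (1+d^2)^-1 (p-q)(z_i - c_k)
        coef = weights.lambda_cluster * 2.0 / n * (w * (p - q))
        diff = Z[:, None, :] - centers[None, :, :]
        dZ += (coef[:, :, None] * diff).sum(axis=1)
        g["C"] = -(coef[:, :, None] * diff).sum(axis=0)

    dZf = dZ[:, :hf].copy()
    dZg = dZ[:, hf:].copy()

    # adjacency BCE
    sig = _sigmoid(logits)
    Gl = (weights.lambda_gcn / (n * n)) * (
        -pos_weight * At * (1.0 - sig) + (1.0 - At) * sig)
    dZg += (Gl + Gl.T) @ Zg

    dmu = dZg + weights.lambda_gcn / n * mu
    dls = (dZg * eps * sg if sample else np.zeros_like(ls)) \
        + weights.lambda_gcn / n * (sg ** 2 - 1.0)
    dP2 = dmu @ params["Wmu"].T + dls @ params["Wsg"].T
    g["Wmu"] = P2.T @ dmu
    g["Wsg"] = P2.T @ dls
    dHg = S.T @ dP2
    dB0 = dHg * (B0 > 0)
    g["W0"] = P1.T @ dB0
    dP1 = dB0 @ params["W0"].T
    dZf += S.T @ dP1

    dA2 = dZf * (A2 > 0)
    g["W2"] = H1.T @ dA2
    g["b2"] = dA2.sum(0)
    dA1 = (dA2 @ params["W2"].T) * (A1 > 0)
    g["W1"] = Xp.T @ dA1
    g["b1"] = dA1.sum(0)
    if U.size:
        dXp = dA1 @ params["W1"].T
        g["T"][U] = dXp[U]
        if dT_self is not None:
            g["T"][U] += weights.lambda_self * 2.0 / U.size * dT_self
    return terms, g


class Adam:
    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for k, gk in grads.items():
            if k not in self.m:
                self.m[k] = np.zeros_like(gk)
                self.v[k] = np.zeros_like(gk)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk ** 2
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


# --------------------------------------------------------------------------
# training stages
# --------------------------------------------------------------------------

def _prep(ds_X, graph):
    S = normalized_propagation(graph.adjacency)
    n = graph.adjacency.shape[0]
    At = np.asarray(graph.adjacency.todense(), dtype=float)
    np.fill_diagonal(At, 1.0)       # self-loops as positive targets
    n_pos = At.sum()
    pos_weight = (n * n - n_pos) / max(n_pos, 1.0)
    return S, At, pos_weight


def _infer(params, X, graph, S, cfg, losses) -> JointEmbedding:
    Zf = encode_features(X, params)
    mu, ls, Zg = encode_graph_vgae(Zf, graph, params, sample=False, S=S)
    Z = np.concatenate([Zf, Zg], axis=1)
    return JointEmbedding(Zf=Zf, Zg=Zg, Z=Z, mu=mu, log_sigma=ls,
                          losses=losses, params=params, config=cfg)


def pretrain(ds, graph: SpatialGraph, cfg: EncoderConfig = None,
             weights: LossWeights = None) -> JointEmbedding:
    """Stage-1 training (rec + gcn + mask-reconstruction objectives)."""
    cfg = cfg or EncoderConfig()
    weights = weights or LossWeights()
    X = np.asarray(ds.X if hasattr(ds, "X") else ds, dtype=float)
    n, m = X.shape
    rng = np.random.default_rng(cfg.seed)
    params = init_params(n, m, cfg)
    _, spec = mask_expression(X, cfg.mask_fraction, cfg.seed, tokens=params["T"])
    S, At, pw = _prep(X, graph)
    opt = Adam(params, lr=cfg.lr)
    losses = []
    for epoch in range(cfg.epochs_pretrain):
        eps = rng.standard_normal((n, cfg.hg))
        terms, grads = loss_and_grads(
            params, X, spec.mask_set, S, At, pw, weights, eps,
            stage="pretrain", use_mask=True, sample=True)
        if not np.isfinite(terms["total"]):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        opt.step(params, grads)
        losses.append({"epoch": epoch, "stage": "pretrain", **terms})
    return _infer(params, X, graph, S, cfg, losses)


def finetune_with_clustering(emb: JointEmbedding, ds, graph: SpatialGraph,
                             cfg: EncoderConfig = None,
                             weights: LossWeights = None) -> JointEmbedding:
    """Stage-2 training: mask objective removed, DEC clustering loss added.

    K-means (k = cfg.n_clusters, seeded) on the pretrained embedding
    initializes the cluster centers, which are trained jointly.
    """
    cfg = cfg or emb.config or EncoderConfig()
    weights = weights or LossWeights()
    X = np.asarray(ds.X if hasattr(ds, "X") else ds, dtype=float)
    n = X.shape[0]
    if cfg.n_clusters > n:
        raise ValueError(f"n_clusters={cfg.n_clusters} exceeds n={n}")
    params = {k: v.copy() for k, v in emb.params.items()}
    km = KMeans(n_clusters=cfg.n_clusters, random_state=cfg.seed, n_init=10)
    km.fit(emb.Z)
    params["C"] = km.cluster_centers_.copy()
    S, At, pw = _prep(X, graph)
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(params, lr=cfg.lr)
    losses = list(emb.losses)
    empty = np.array([], dtype=int)
    for epoch in range(cfg.epochs_finetune):
        eps = rng.standard_normal((n, cfg.hg))
        terms, grads = loss_and_grads(
            params, X, empty, S, At, pw, weights, eps,
            stage="finetune", cluster_p=None, centers=params["C"],
            use_mask=False, sample=True)
        if not np.isfinite(terms["total"]):
            raise FloatingPointError(f"training diverged at epoch {epoch}")
        opt.step(params, grads)
        losses.append({"epoch": epoch, "stage": "finetune", **terms})
    return _infer(params, X, graph, S, cfg, losses)


def fit_embedding(ds, graph: SpatialGraph, cfg: EncoderConfig = None,
                  weights: LossWeights = None,
                  finetune: bool = True) -> JointEmbedding:
    """Convenience wrapper: pretrain then (optionally) fine-tune."""
    emb = pretrain(ds, graph, cfg, weights)
    if finetune:
        emb = finetune_with_clustering(emb, ds, graph, cfg, weights)
    return emb


def pca_embedding(X: np.ndarray, n_components: int, seed: int = 2025) -> np.ndarray:
    """Raw-expression PCA stand-in for Z (embedding-free ablation)."""
    from sklearn.decomposition import PCA

    n_components = min(n_components, min(X.shape) - 1)
    return PCA(n_components=n_components, random_state=seed).fit_transform(
        np.asarray(X, dtype=float))


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------

def save_checkpoint(emb: JointEmbedding, path: str) -> None:
    cfg = emb.config or EncoderConfig()
    np.savez(path, __config__=json.dumps(cfg.__dict__),
             **{k: v for k, v in emb.params.items()})


def load_checkpoint(path: str):
    with np.load(path, allow_pickle=False) as z:
        cfg = EncoderConfig(**json.loads(str(z["__config__"])))
        params = {k: z[k] for k in z.files if k != "__config__"}
    return params, cfg
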