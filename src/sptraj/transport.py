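"""Entropy-regularized optimal transport on the fused cost.

The cell-cell transition structure is the solution of

    min_P  <P, M>_F + gamma * sum_ij P_ij log P_ij
    s.t.   P 1 = a,  P^T 1 = b,  a = b = (1/n) 1,

solved by Sinkhorn iterations in the log domain (mandatory here: the
diagonal of the cost is raised to d_diag = 1e6 to suppress self-transitions,
and exp(-1e6/gamma) underflows any naive scaling).  The raw plan P has
entries summing to 1; consumers that need "transition probability from cell
i" row-normalize it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["TransitionMatrix", "build_cost_with_diagonal", "sinkhorn_transition",
           "row_stochastic"]


@dataclass
class TransitionMatrix:
    P: np.ndarray
    gamma: float
    d_diag: float
    marginal_a: np.ndarray
    marginal_b: np.ndarray
    n_iter: int
    converged: bool

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def max_marginal_violation(self) -> float:
        a_err = np.abs(self.P.sum(axis=1) - self.marginal_a).max()
        b_err = np.abs(self.P.sum(axis=0) - self.marginal_b).max()
        return float(max(a_err, b_err))

    def sparsify(self, threshold: float = 1e-12):
        import scipy.sparse as sp

        Q = self.P.copy()
        Q[Q < threshold] = 0.0
        return sp.csr_matrix(Q)


def build_cost_with_diagonal(M, d_diag: float = 1e6) -> np.ndarray:
    """Copy the fused cost and set its diagonal to the suppression constant."""
    M = np.asarray(getattr(M, "M", M), dtype=float)
    C = M.copy()
    off = C[~np.eye(C.shape[0], dtype=bool)]
    if off.size and d_diag <= off.max():
        warnings.warn(
            f"d_diag={d_diag} does not exceed the largest off-diagonal cost "
            f"({off.max():.3g}); self-transition suppression is ineffective")
    np.fill_diagonal(C, d_diag)
    return C


def sinkhorn_transition(cost: np.ndarray, gamma: float = 0.1,
                        tol: float = 1e-9, max_iter: int = 10_000,
                        d_diag: float = None) -> TransitionMatrix:
    """Log-domain Sinkhorn under uniform marginals a = b = 1/n.

    Convergence is declared when the largest marginal violation of the
    reconstructed plan falls below ``tol``; non-convergence returns the last
    iterate with ``converged=False`` and a warning.
    """
    C = np.asarray(cost, dtype=float)
    if not np.isfinite(C).all():
        raise ValueError("cost matrix must be finite")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    n = C.shape[0]
    log_a = np.full(n, -np.log(n))
    log_b = np.full(n, -np.log(n))
    logK = -C / gamma
    f = np.zeros(n)   # log row scalings
    g = np.zeros(n)   # log col scalings
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = log_a - logsumexp(logK + g[None, :], axis=1)
        g = log_b - logsumexp(logK + f[:, None], axis=0)
        if it % 10 == 0 or it == max_iter:
            logP = f[:, None] + logK + g[None, :]
            P = np.exp(logP)
            err = max(np.abs(P.sum(1) - 1.0 / n).max(),
                      np.abs(P.sum(0) - 1.0 / n).max())
            if err < tol:
                converged = True
                break
    else:  # pragma: no cover - loop always breaks via the check above
        pass
    logP = f[:, None] + logK + g[None, :]
    P = np.exp(logP)
    if not converged:
        warnings.warn(f"Sinkhorn did not reach tol={tol} in {max_iter} iterations")
    return TransitionMatrix(
        P=P, gamma=float(gamma),
        d_diag=float(d_diag) if d_diag is not None else float(np.diag(C).max()),
        marginal_a=np.full(n, 1.0 / n), marginal_b=np.full(n, 1.0 / n),
        n_iter=it, converged=converged)


def row_stochastic(P: np.ndarray) -> np.ndarray:
    """Rescale a transport plan so every row sums to one."""
    P = np.asarray(getattr(P, "P", P), dtype=float)
    s = P.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return P / s
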