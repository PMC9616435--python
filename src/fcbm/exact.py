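"""Exact maximum-entropy multipliers by damped fixed-point iteration.

The maximum-entropy distribution subject to expected block-pair link
counts and expected degrees factorizes over edges, with

    p_ij = x_i x_j y_{I_i J_j} / (1 + x_i x_j y_{I_i J_j}),   p_ii = 0,

where ``x_i`` and ``y_IJ`` are exponentiated Lagrange multipliers.  They
solve the nonlinear system matching every expected degree and block-pair
count to its target.  We solve it with a coordinate-wise fixed-point
scheme of the kind standard for maximum-entropy graph ensembles:

    x_i  <- k_i  / sum_{j != i} x_j y_{IJ} / (1 + x_i x_j y_{IJ})
    y_IJ <- K_IJ / sum_{i in I, j in J, i != j} x_i x_j / (1 + x_i x_j y_IJ)

initialized at the sparse closed form (exact in the p -> 0 limit), with
geometric damping in log-space if the residual stalls.  Vertices with
``k_i = 0`` are pinned at ``x_i = 0`` and block pairs with ``K_IJ = 0`` at
``y_IJ = 0``; both are limits of the system.  After convergence the x/y
scale degeneracy is fixed by rescaling so that ``sum_{i in I} x_i`` equals
``sum_{i in I} k_i`` in every block, which leaves all p_ij unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockPartition, ConstraintSet
from .sparse import sparse_multipliers_dcbm

__all__ = [
    "MultiplierSet",
    "SolverReport",
    "edge_probability",
    "probability_matrix",
    "residuals",
    "solve_fcbm",
    "solve_dcbm",
]


@dataclass(frozen=True)
class MultiplierSet:
    """Exponentiated multipliers: per-vertex ``x`` and block-pair ``y``."""

    x: np.ndarray
    y: np.ndarray
    part: BlockPartition

    def probability(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        a = self.part.assignment
        return edge_probability(self.x[i], self.x[j], self.y[a[i], a[j]])

    def probability_block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Dense probability sub-matrix for ``rows`` x ``cols``."""
        a = self.part.assignment
        t = np.outer(self.x[rows], self.x[cols]) * self.y[np.ix_(a[rows], a[cols])]
        p = t / (1.0 + t)
        p[np.equal.outer(rows, cols)] = 0.0
        return p


@dataclass(frozen=True)
class SolverReport:
    converged: bool
    iterations: int
    max_residual: float
    residual_norm: float
    tol: float


def edge_probability(x_i: float, x_j: float, y_IJ: float, same_vertex: bool = False) -> float:
    """Exact edge probability; 0 for a vertex with itself."""
    if same_vertex:
        return 0.0
    t = x_i * x_j * y_IJ
    return t / (1.0 + t)


def probability_matrix(m: MultiplierSet) -> np.ndarray:
    """Full dense ``p_ij`` matrix (zero diagonal). O(N^2) memory."""
    idx = np.arange(m.part.N)
    return m.probability_block(idx, idx)


def _scaled_residuals(P: np.ndarray, c: ConstraintSet, part: BlockPartition):
    """Raw residual matrices plus the convergence scale (relative for
    constraints above 1, absolute below)."""
    a = part.assignment
    n = part.n
    deg = P.sum(axis=1)
    # block-pair sums of P with the doubled-diagonal convention
    M = np.zeros((n, part.N))
    np.add.at(M, a, P)
    L = np.zeros((n, n))
    np.add.at(L.T, a, M.T)
    r_K = L - c.K
    r_k = deg - c.k
    s_K = r_K / np.maximum(c.K, 1.0)
    s_k = r_k / np.maximum(c.k, 1.0)
    return r_K, r_k, s_K, s_k


def residuals(m: MultiplierSet, c: ConstraintSet, part: BlockPartition):
    """Constraint violations of a multiplier set.

    Returns ``(block-pair residual matrix, per-vertex residual vector)``
    where the matrix entry ``(I, J)`` is ``sum_{i in I, j in J, i != j}
    p_ij - K_IJ`` (diagonal doubled) and the vector entry ``i`` is
    ``sum_j p_ij - k_i``.
    """
    P = probability_matrix(m)
    r_K, r_k, _, _ = _scaled_residuals(P, c, part)
    return r_K, r_k


def _iterate(
    c: ConstraintSet,
    part: BlockPartition,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, SolverReport]:
    a = part.assignment
    n = part.n
    start = sparse_multipliers_dcbm(c, part)
    x = start.x.astype(float).copy()
    y = start.y.astype(float).copy()
    free_x = c.k > 0
    free_y = c.K > 0
    x[~free_x] = 0.0
    y[~free_y] = 0.0

    damping = 1.0
    prev_res = np.inf
    max_res = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        t = np.outer(x, x) * y[np.ix_(a, a)]
        denom = 1.0 + t
        # x-update: k_i / sum_{j != i} x_j y_IJ / (1 + t_ij)
        W = y[np.ix_(a, a)] * x[None, :] / denom
        np.fill_diagonal(W, 0.0)
        sx = W.sum(axis=1)
        x_new = np.where(free_x & (sx > 0), c.k / np.where(sx > 0, sx, 1.0), 0.0)
        if damping < 1.0:
            pos = free_x & (x > 0) & (x_new > 0)
            x_new[pos] = x[pos] * (x_new[pos] / x[pos]) ** damping
        x = x_new

        # y-update with fresh x
        U = np.outer(x, x)
        t = U * y[np.ix_(a, a)]
        G = U / (1.0 + t)
        np.fill_diagonal(G, 0.0)
        M = np.zeros((n, part.N))
        np.add.at(M, a, G)
        S = np.zeros((n, n))
        np.add.at(S.T, a, M.T)
        y_new = np.where(free_y & (S > 0), c.K / np.where(S > 0, S, 1.0), 0.0)
        if damping < 1.0:
            pos = free_y & (y > 0) & (y_new > 0)
            y_new[pos] = y[pos] * (y_new[pos] / y[pos]) ** damping
        y = y_new
        # renormalize the gauge every sweep so the x/y scale degeneracy
        # cannot drift toward overflow/underflow
        x, y = _fix_gauge(x, y, c, part)

        t = np.outer(x, x) * y[np.ix_(a, a)]
        P = t / (1.0 + t)
        np.fill_diagonal(P, 0.0)
        _, _, s_K, s_k = _scaled_residuals(P, c, part)
        max_res = max(np.abs(s_K).max(), np.abs(s_k).max())
        if max_res <= tol:
            break
        # stalling or oscillation: increase damping
        if max_res > 0.95 * prev_res:
            damping = max(0.25, damping * 0.7)
        prev_res = max_res

    norm = float(np.sqrt((s_K**2).sum() + (s_k**2).sum()))
    report = SolverReport(
        converged=bool(max_res <= tol),
        iterations=it,
        max_residual=float(max_res),
        residual_norm=norm,
        tol=tol,
    )
    return x, y, report


def _fix_gauge(x: np.ndarray, y: np.ndarray, c: ConstraintSet, part: BlockPartition):
    """Rescale per block so sum_{i in I} x_i = sum_{i in I} k_i; p_ij invariant."""
    bx = np.bincount(part.assignment, weights=x, minlength=part.n)
    bk = np.bincount(part.assignment, weights=c.k, minlength=part.n)
    scale = np.where(bx > 0, bk / np.where(bx > 0, bx, 1.0), 1.0)
    x = x * scale[part.assignment]
    y = y / np.outer(scale, scale)
    y[c.K == 0] = 0.0
    return x, y


def solve_dcbm(
    c: ConstraintSet,
    part: BlockPartition,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = None,
) -> tuple[MultiplierSet, SolverReport]:
    """Solve for the exact multipliers given expected ``K`` and ``k``.

    Deterministic: the iteration is initialized at the sparse closed form
    and involves no randomness (``seed`` is accepted for interface
    symmetry and ignored).  Non-convergence is reported, never silent.
    """
    x, y, report = _iterate(c, part, tol, max_iter)
    x, y = _fix_gauge(x, y, c, part)
    return MultiplierSet(x=x, y=y, part=part), report


def solve_fcbm(
    c: ConstraintSet,
    part: BlockPartition,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    seed: int | None = None,
) -> tuple[MultiplierSet, SolverReport]:
    """Solve the tunable-density model (requires ``c.p``); same contract
    as :func:`solve_dcbm`."""
    if c.p is None:
        raise ValueError("constraint set has no density parameter p")
    return solve_dcbm(c, part, tol=tol, max_iter=max_iter, seed=seed)
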