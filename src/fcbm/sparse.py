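"""Closed-form multipliers for the sparse regime (p << 1).

When the network is sparse the exact edge probability
``x_i x_j y_IJ / (1 + x_i x_j y_IJ)`` linearizes to ``x_i x_j y_IJ`` and
the constraint system admits a closed-form solution: ``x_i = k_i`` and
``y_IJ = K_IJ / (D_I D_J)`` with ``D_I`` the expected total degree of
block ``I``.  The printed closed form drops the "j != i" self-exclusion
inside the block sums, an O(1/N_I) approximation valid for large blocks;
we adopt it as printed.  Products exceeding 1 (possible under heavy-tailed
fitness) are clipped to 1 and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .blocks import BlockPartition, ConstraintSet

__all__ = [
    "SparseEdgeModel",
    "sparse_multipliers_fcbm",
    "sparse_multipliers_dcbm",
    "sparse_edge_probability",
]


@dataclass(frozen=True)
class SparseEdgeModel:
    """Sparse-regime multipliers; emits ``min(x_i x_j y_IJ, 1)``."""

    x: np.ndarray
    y: np.ndarray
    part: BlockPartition

    def probability(self, i: int, j: int) -> float:
        return sparse_edge_probability(self, i, j)

    def probability_block(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Dense probability sub-matrix for ``rows`` x ``cols`` (clipped)."""
        a = self.part.assignment
        raw = np.outer(self.x[rows], self.x[cols]) * self.y[
            np.ix_(a[rows], a[cols])
        ]
        np.clip(raw, 0.0, 1.0, out=raw)
        raw[np.equal.outer(rows, cols)] = 0.0
        return raw

    def clipped_pairs(self) -> int:
        """Number of unordered pairs whose raw product exceeds 1."""
        ordered = 0
        n = self.part.N
        a = self.part.assignment
        for start in range(0, n, 2048):
            rows = np.arange(start, min(start + 2048, n))
            raw = np.outer(self.x[rows], self.x) * self.y[np.ix_(a[rows], a)]
            raw[np.equal.outer(rows, np.arange(n))] = 0.0
            ordered += int((raw > 1.0).sum())
        # raw matrix is symmetric, so ordered count is twice the pair count
        return ordered // 2

    def max_product(self) -> float:
        """Largest raw ``x_i x_j y`` over distinct pairs (sparsity
        diagnostic), scanned over the 256 highest-x vertices where the
        maximum is attained up to rare cross-block ``y`` extremes."""
        a = self.part.assignment
        order = np.argsort(self.x)[::-1][: min(self.part.N, 256)]
        raw = np.outer(self.x[order], self.x[order]) * self.y[
            np.ix_(a[order], a[order])
        ]
        np.fill_diagonal(raw, 0.0)
        return float(raw.max(initial=0.0))


def sparse_multipliers_dcbm(c: ConstraintSet, part: BlockPartition) -> SparseEdgeModel:
    """Sparse closed form from directly supplied ``K`` and ``k``."""
    D = c.block_degree_totals()
    K = c.K
    if ((D == 0) & (K.sum(axis=1) > 0)).any():
        raise ValueError("block with zero total degree but non-zero K row")
    denom = np.outer(D, D)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(denom > 0, K / np.where(denom > 0, denom, 1.0), 0.0)
    return SparseEdgeModel(x=c.k.copy(), y=y, part=part)


def sparse_multipliers_fcbm(c: ConstraintSet, part: BlockPartition) -> SparseEdgeModel:
    """Sparse closed form for the tunable-density model.

    Identical arithmetic to the DCBM form because ``K`` and ``k`` already
    encode ``p``, the mixing densities and the fitness shares; kept separate
    so the density parameter is validated as present.
    """
    if c.p is None:
        raise ValueError("constraint set has no density parameter p")
    return sparse_multipliers_dcbm(c, part)


def sparse_edge_probability(model: SparseEdgeModel, i: int, j: int) -> float:
    """``min(x_i x_j y, 1)`` for distinct vertices, 0 on the diagonal."""
    if i == j:
        return 0.0
    a = model.part.assignment
    return float(min(model.x[i] * model.x[j] * model.y[a[i], a[j]], 1.0))
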