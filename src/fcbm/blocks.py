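"""Block partitions, mixing-density matrices and expectation constraints.

The model lives on the ensemble of simple undirected graphs on ``N``
vertices partitioned into ``n`` blocks.  Two families of soft constraints
define it: the expected number of links between every block pair, and the
expected degree of every vertex.  Throughout the package the diagonal of
every block-pair count matrix (``N_IJ``, ``K_IJ``, ``L_IJ``) stores *twice*
the number of intra-block pairs/edges, so that ``sum_J K_IJ`` equals the
expected total degree of block ``I`` without special-casing the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "BlockPartition",
    "MixingDensityMatrix",
    "ConstraintSet",
    "validate_fitness",
    "build_constraints",
    "constraints_from_graph",
    "density_from_mean_degree",
]

#: absolute tolerance for the ordered-sum normalization of Delta
DELTA_SUM_ATOL = 1e-12
#: relative tolerance for the block/degree consistency identity
CONSISTENCY_RTOL = 1e-9


@dataclass(frozen=True)
class BlockPartition:
    """Partition of ``N`` vertices into ``n`` non-empty blocks.

    Parameters
    ----------
    assignment : array of int, shape (N,)
        Block index of each vertex, values in ``{0..n-1}``.
    n : int, optional
        Number of blocks; inferred as ``assignment.max() + 1`` if omitted.
    """

    assignment: np.ndarray
    n: int = 0
    sizes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=np.int64)
        if a.ndim != 1 or a.size < 2:
            raise ValueError("assignment must be a 1-D array with N >= 2")
        n = int(a.max()) + 1 if self.n == 0 else int(self.n)
        if a.min() < 0 or a.max() >= n:
            raise ValueError("block indices must lie in {0..n-1}")
        sizes = np.bincount(a, minlength=n)
        if (sizes == 0).any():
            raise ValueError("every block must be non-empty")
        object.__setattr__(self, "assignment", a)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "sizes", sizes)

    @property
    def N(self) -> int:
        return int(self.assignment.size)

    def pair_counts(self) -> np.ndarray:
        """Ordered pair counts ``N_IJ``; diagonal is ``N_I (N_I - 1)``."""
        s = self.sizes.astype(float)
        counts = np.outer(s, s)
        np.fill_diagonal(counts, s * (s - 1.0))
        return counts

    def members(self, I: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == I)


@dataclass(frozen=True)
class MixingDensityMatrix:
    """Symmetric non-negative block-mixing densities with ordered sum 2.

    The ordered sum over all ``(I, J)`` entries (diagonal counted once,
    off-diagonal twice by symmetry) must equal 2, so that the constraint
    matrix ``K = p * C(N,2) * delta`` sums to ``p * N * (N-1)``.
    """

    delta: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.delta, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("delta must be square")
        if not np.allclose(d, d.T, rtol=0, atol=1e-12):
            raise ValueError("delta must be symmetric")
        if (d < 0).any():
            raise ValueError("delta entries must be non-negative")
        if abs(d.sum() - 2.0) > DELTA_SUM_ATOL * max(1.0, d.shape[0]):
            raise ValueError(
                f"ordered sum of delta must be 2, got {d.sum()!r}"
            )
        object.__setattr__(self, "delta", d)

    @property
    def n(self) -> int:
        return self.delta.shape[0]


def validate_fitness(f: np.ndarray) -> np.ndarray:
    """Validate a fitness vector: strictly positive, finite."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 1:
        raise ValueError("fitness must be a 1-D array")
    if not np.isfinite(f).all() or (f <= 0).any():
        raise ValueError("fitness values must be positive and finite")
    return f


@dataclass(frozen=True)
class ConstraintSet:
    """Target expectations: block-pair link counts ``K`` and degrees ``k``.

    ``K`` is symmetric with the doubled-diagonal convention.  ``p`` is the
    global density when the constraints come from the tunable-density model;
    it is ``None`` when they were measured on an observed graph.
    """

    K: np.ndarray
    k: np.ndarray
    part: BlockPartition
    p: float | None = None

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        k = np.asarray(self.k, dtype=float)
        part = self.part
        if K.shape != (part.n, part.n):
            raise ValueError("K has wrong shape")
        if k.shape != (part.N,):
            raise ValueError("k has wrong shape")
        if not np.allclose(K, K.T, rtol=0, atol=1e-12):
            raise ValueError("K must be symmetric")
        if (K < 0).any() or (k < 0).any():
            raise ValueError("constraints must be non-negative")
        # feasibility: no expectation may exceed what simple graphs allow
        if (k > part.N - 1 + 1e-12).any():
            bad = int(np.argmax(k))
            raise ValueError(
                f"infeasible: k[{bad}]={k[bad]} exceeds N-1={part.N - 1}"
            )
        counts = part.pair_counts()
        if (K > counts + 1e-9 * np.maximum(counts, 1.0)).any():
            I, J = np.unravel_index(int(np.argmax(K - counts)), K.shape)
            raise ValueError(
                f"infeasible: K[{I},{J}]={K[I, J]} exceeds N_IJ={counts[I, J]}"
            )
        # consistency identity: row sums of K match block degree totals
        row = K.sum(axis=1)
        blk = np.bincount(part.assignment, weights=k, minlength=part.n)
        if not np.allclose(row, blk, rtol=CONSISTENCY_RTOL, atol=1e-9):
            raise ValueError(
                "inconsistent constraints: sum_J K_IJ != sum_{i in I} k_i"
            )
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "k", k)

    def block_degree_totals(self) -> np.ndarray:
        """Expected total degree of each block, ``sum_J K_IJ``."""
        return self.K.sum(axis=1)


def density_from_mean_degree(mu: float, N: int) -> float:
    """Density ``p`` giving network mean degree ``mu`` on ``N`` vertices.

    The total expected degree is ``p * N * (N-1)`` because the mixing
    densities sum to 2, hence ``p = mu / (N - 1)``.
    """
    if not 0 < mu < N - 1:
        raise ValueError(f"mean degree must lie in (0, N-1); got {mu}")
    return mu / (N - 1)


def build_constraints(
    p: float,
    delta: MixingDensityMatrix,
    f: np.ndarray,
    part: BlockPartition,
) -> ConstraintSet:
    """Assemble the tunable-density constraint set.

    ``K_IJ = p C(N,2) delta_IJ`` and
    ``k_i = p C(N,2) (f_i / sum_{u in I_i} f_u) sum_J delta_{I_i J}``.
    The fitness enters only through its within-block share, so rescaling
    ``f`` by any positive constant leaves the constraints unchanged.
    """
    if not 0 < p < 1:
        raise ValueError("density p must lie in (0, 1)")
    if delta.n != part.n:
        raise ValueError("delta and partition disagree on block count")
    f = validate_fitness(f)
    if f.shape != (part.N,):
        raise ValueError("fitness has wrong length")
    # singleton blocks have no intra pair: a positive intra density is
    # unsatisfiable by any simple graph
    singleton = part.sizes == 1
    if (np.diag(delta.delta)[singleton] > 0).any():
        raise ValueError("positive intra-block density on a singleton block")

    pairs = p * (part.N * (part.N - 1) / 2.0)
    K = pairs * delta.delta
    block_f = np.bincount(part.assignment, weights=f, minlength=part.n)
    share = f / block_f[part.assignment]
    k = pairs * share * delta.delta.sum(axis=1)[part.assignment]
    return ConstraintSet(K=K, k=k, part=part, p=p)


def constraints_from_graph(g: nx.Graph, part: BlockPartition) -> ConstraintSet:
    """Measure ``K`` and ``k`` on an observed simple graph (DCBM use-case).

    ``K_IJ`` is the observed inter-block edge count (diagonal doubled) and
    ``k_i`` the observed degree, so the consistency identity holds exactly.
    """
    if nx.number_of_selfloops(g):
        raise ValueError("graph must be simple (no self-loops)")
    N = part.N
    if g.number_of_nodes() > N or any(not (0 <= v < N) for v in g.nodes):
        raise ValueError("partition does not cover the graph's vertices")
    a = part.assignment
    K = np.zeros((part.n, part.n))
    k = np.zeros(N)
    for u, v in g.edges():
        I, J = a[u], a[v]
        K[I, J] += 1.0
        K[J, I] += 1.0
        k[u] += 1.0
        k[v] += 1.0
    return ConstraintSet(K=K, k=k, part=part, p=None)
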