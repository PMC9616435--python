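"""Bernoulli sampling of simple graphs from an edge-probability model.

Because the maximum-entropy distribution factorizes over edges, sampling
a graph is one independent Bernoulli trial per unordered vertex pair.
The pair loop is vectorized in row-chunks so that a 10^4-vertex network
(~5x10^7 pairs) fits comfortably in memory.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .blocks import BlockPartition

__all__ = [
    "sample_graph",
    "sample_ensemble",
    "ensemble_block_statistics",
]

_CHUNK = 1024


def _sample_edges(model, rng: np.random.Generator) -> np.ndarray:
    n = model.part.N
    rows_u = []
    rows_v = []
    for start in range(0, n, _CHUNK):
        rows = np.arange(start, min(start + _CHUNK, n))
        # only columns in the strict upper triangle of this row block
        cols = np.arange(start + 1, n)
        if cols.size == 0:
            continue
        P = model.probability_block(rows, cols)
        mask = cols[None, :] > rows[:, None]
        hit = (rng.random(P.shape) < P) & mask
        ui, vi = np.nonzero(hit)
        rows_u.append(rows[ui])
        rows_v.append(cols[vi])
    return np.stack(
        [np.concatenate(rows_u), np.concatenate(rows_v)], axis=1
    ) if rows_u else np.empty((0, 2), dtype=int)


def sample_graph(model, seed) -> nx.Graph:
    """Draw one simple undirected graph.

    ``model`` is anything exposing ``part`` and
    ``probability_block(rows, cols)`` — an exact :class:`MultiplierSet`
    or a :class:`SparseEdgeModel`.  ``seed`` may be an int or a
    ``numpy.random.Generator``/``SeedSequence``.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(range(model.part.N))
    g.add_edges_from(map(tuple, _sample_edges(model, rng)))
    return g


def sample_ensemble(model, n_graphs: int, seed) -> list[nx.Graph]:
    """Draw ``n_graphs`` independent graphs from per-graph child streams.

    A root ``SeedSequence`` spawns one child per graph, so the ensemble is
    reproducible from ``(seed, n_graphs)`` and the streams are independent.
    """
    if n_graphs < 1:
        raise ValueError("n_graphs must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [sample_graph(model, child) for child in root.spawn(n_graphs)]


def ensemble_block_statistics(graphs, part: BlockPartition):
    """Empirical means of block-pair link counts and degrees.

    Returns ``(L_mean, deg_mean)`` where ``L_mean`` follows the
    doubled-diagonal convention (intra-block entries count each edge
    twice), directly comparable to a constraint matrix ``K``.
    """
    a = part.assignment
    n = part.n
    L = np.zeros((n, n))
    deg = np.zeros(part.N)
    m = 0
    for g in graphs:
        if g.number_of_nodes() != part.N:
            raise ValueError("graphs must share the partition's vertex count")
        for u, v in g.edges():
            I, J = a[u], a[v]
            L[I, J] += 1.0
            L[J, I] += 1.0
            deg[u] += 1.0
            deg[v] += 1.0
        m += 1
    return L / m, deg / m
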