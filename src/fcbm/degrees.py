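"""Fitness distributions and closed-form degree-distribution estimators.

In the sparse regime, a vertex of fitness ``f`` in block ``I`` has
expected degree ``k(f, I) ~= f * mu_I / <f>`` where ``mu_I`` is the
block's expected mean degree and ``<f>`` the analytic mean of the fitness
distribution.  Inverting this change of variables gives two estimates of
the network degree density:

* block-resolved:  ``p_k(k) = (<f>/N) sum_I p_f(k <f>/mu_I) N_I/mu_I``
* global (simpler): ``p_k(k) = p_f(k <f>/mu) <f>/mu``

so the degree distribution inherits the shape of the fitness distribution
(power-law, lognormal or exponential fitness give degrees of the same
family).  Empirical degrees are integers, so for comparisons both
estimators are evaluated on the integer grid and renormalized there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .blocks import BlockPartition, ConstraintSet

__all__ = [
    "FitnessDistribution",
    "DegreeDistributionEstimate",
    "block_mean_degrees",
    "degree_pdf_blockwise",
    "degree_pdf_global",
    "sample_fitness",
    "empirical_degree_distribution",
    "ks_distance",
]


@dataclass(frozen=True)
class FitnessDistribution:
    """A named positive fitness distribution with finite mean.

    Families and parameters:

    * ``pareto``: ``shape`` a > 1 (finite mean), ``scale`` x_m > 0
    * ``lognormal``: ``mu`` (log-mean), ``sigma`` (log-sd > 0)
    * ``exponential``: ``rate`` lambda > 0
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        defaults = {
            "pareto": {"shape": 2.5, "scale": 1.0},
            "lognormal": {"mu": 0.0, "sigma": 1.0},
            "exponential": {"rate": 1.0},
        }
        if self.family not in defaults:
            raise ValueError(f"unknown fitness family {self.family!r}")
        merged = {**defaults[self.family], **self.params}
        if self.family == "pareto" and merged["shape"] <= 1:
            raise ValueError("pareto shape must exceed 1 for a finite mean")
        if any(v <= 0 for k, v in merged.items() if k != "mu"):
            raise ValueError("distribution parameters must be positive")
        object.__setattr__(self, "params", merged)

    def _frozen(self):
        p = self.params
        if self.family == "pareto":
            return stats.pareto(b=p["shape"], scale=p["scale"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["sigma"], scale=np.exp(p["mu"]))
        return stats.expon(scale=1.0 / p["rate"])

    @property
    def mean(self) -> float:
        """Analytic expectation of the fitness."""
        return float(self._frozen().mean())

    def pdf(self, f):
        return self._frozen().pdf(f)

    def sample(self, N: int, seed) -> np.ndarray:
        return sample_fitness(self, N, seed)


def sample_fitness(fd: FitnessDistribution, N: int, seed) -> np.ndarray:
    """Draw ``N`` i.i.d. positive fitness values, reproducible by seed."""
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    return fd._frozen().rvs(size=N, random_state=rng)


@dataclass(frozen=True)
class DegreeDistributionEstimate:
    """Callable degree density with metadata on which estimator built it."""

    evaluator: object
    estimator: str
    mu: float | None = None
    block_mus: np.ndarray | None = None

    def __call__(self, k):
        return self.evaluator(np.asarray(k, dtype=float))

    def pmf_grid(self, k_max: int) -> np.ndarray:
        """Density at integer degrees 0..k_max, renormalized to sum 1."""
        grid = np.arange(k_max + 1, dtype=float)
        vals = np.asarray(self(grid), dtype=float)
        total = vals.sum()
        if total <= 0:
            raise ValueError("estimate vanishes on the requested grid")
        return vals / total


def block_mean_degrees(c: ConstraintSet, part: BlockPartition) -> np.ndarray:
    """Expected mean degree per block, ``mu_I = (sum_J K_IJ) / N_I``."""
    return c.block_degree_totals() / part.sizes


def degree_pdf_blockwise(
    fd: FitnessDistribution,
    mus: np.ndarray,
    part: BlockPartition,
) -> DegreeDistributionEstimate:
    """Block-resolved degree-density estimate (the more accurate form).

    Blocks with ``mu_I = 0`` cannot place edges; they contribute a point
    mass ``N_I/N`` at degree 0 (the limit of the change of variables),
    realized on the integer grid as an atom at ``k = 0``.
    """
    mus = np.asarray(mus, dtype=float)
    if mus.shape != (part.n,):
        raise ValueError("one mean degree per block required")
    fmean = fd.mean
    sizes = part.sizes.astype(float)
    N = float(part.N)
    live = mus > 0
    zero_mass = sizes[~live].sum() / N

    def evaluator(k):
        k = np.atleast_1d(np.asarray(k, dtype=float))
        out = np.zeros_like(k)
        for mu_I, N_I in zip(mus[live], sizes[live]):
            out += fd.pdf(k * fmean / mu_I) * N_I / mu_I
        out *= fmean / N
        if zero_mass > 0:
            out = out + np.where(k == 0, zero_mass, 0.0)
        return out

    return DegreeDistributionEstimate(
        evaluator=evaluator, estimator="blockwise", block_mus=mus
    )


def degree_pdf_global(
    fd: FitnessDistribution, mu: float
) -> DegreeDistributionEstimate:
    """Single-scale degree-density estimate from the network mean degree."""
    if mu <= 0:
        raise ValueError("mean degree must be positive")
    fmean = fd.mean

    def evaluator(k):
        k = np.atleast_1d(np.asarray(k, dtype=float))
        return fd.pdf(k * fmean / mu) * fmean / mu

    return DegreeDistributionEstimate(evaluator=evaluator, estimator="global", mu=mu)


def empirical_degree_distribution(graphs) -> np.ndarray:
    """Averaged normalized degree histogram of an ensemble.

    Returns ``pmf`` where ``pmf[k]`` is the ensemble-average fraction of
    vertices with degree ``k``.
    """
    graphs = list(graphs)
    if not graphs:
        raise ValueError("need at least one graph")
    N = graphs[0].number_of_nodes()
    degs = [np.fromiter((d for _, d in g.degree()), dtype=int) for g in graphs]
    if any(g.number_of_nodes() != N for g in graphs):
        raise ValueError("graphs must share the vertex count")
    k_max = max(int(d.max(initial=0)) for d in degs)
    pmf = np.zeros(k_max + 1)
    for d in degs:
        pmf += np.bincount(d, minlength=k_max + 1) / N
    return pmf / len(graphs)


def ks_distance(
    empirical_pmf: np.ndarray,
    estimate: DegreeDistributionEstimate,
    min_degree: int = 0,
) -> float:
    """Kolmogorov-Smirnov distance between an empirical degree histogram
    and a closed-form estimate, both discretized on the integer grid.

    With ``min_degree > 0`` both distributions are restricted to degrees
    ``>= min_degree`` and renormalized before comparison (the closed forms
    are least reliable at very small degrees).
    """
    emp = np.asarray(empirical_pmf, dtype=float)
    k_max = emp.size - 1
    # extend the grid until the estimate's tail mass is negligible
    grid_max = max(k_max, 1)
    model = estimate.pmf_grid(grid_max)
    while model[-1] > 1e-12 and grid_max < 100 * (k_max + 1):
        grid_max *= 2
        model = estimate.pmf_grid(grid_max)
    emp_full = np.zeros(grid_max + 1)
    emp_full[: emp.size] = emp
    if min_degree > 0:
        emp_full[:min_degree] = 0.0
        model = model.copy()
        model[:min_degree] = 0.0
        if emp_full.sum() == 0 or model.sum() == 0:
            raise ValueError("no mass above min_degree")
        emp_full /= emp_full.sum()
        model /= model.sum()
    else:
        emp_full /= emp_full.sum()
    return float(np.abs(np.cumsum(emp_full) - np.cumsum(model)).max())
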