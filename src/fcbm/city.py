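"""Stylized-city configurations: a fully synthetic benchmark territory.

The benchmark emulates an idealized urban area: ``N`` inhabitants on a
disk of radius 2.5 km tessellated into 0.5 km tiles, an age-stratified
population with an assortative age-contact matrix, gravity-style
distance decay with ``beta = 1``, and a density tuned so the network
mean degree is 25.  Three spatial densities (uniform, radially
increasing, radially decreasing) cross three fitness families (pareto,
lognormal, exponential) give the nine benchmark configurations.

All inputs are generated in code — the age pyramid and contact matrix
are synthetic stand-ins for survey/census data, shaped like their
real-world counterparts (assortative, diagonally dominant contacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .blocks import (
    BlockPartition,
    ConstraintSet,
    MixingDensityMatrix,
    build_constraints,
    density_from_mean_degree,
)
from .degrees import FitnessDistribution
from .spatial import (
    AgeStructure,
    SocialMixingMatrix,
    Tessellation,
    build_delta,
    distance_matrix,
    mixing_matrix_from_contacts,
    sample_population,
    tessellate_disk,
    SPATIAL_DENSITIES,
)

__all__ = [
    "CityConfig",
    "CityRealization",
    "paper_city_configs",
    "benchmark_city_configs",
    "synthetic_contact_matrix",
    "default_age_structure",
    "build_city",
]

FITNESS_FAMILIES = ("pareto", "lognormal", "exponential")

#: synthetic five-band age pyramid (stand-in for census data)
DEFAULT_AGE_FRACTIONS = (0.15, 0.20, 0.25, 0.25, 0.15)
DEFAULT_AGE_GROUPS = ("0-14", "15-29", "30-44", "45-64", "65+")


def default_age_structure() -> AgeStructure:
    return AgeStructure(groups=DEFAULT_AGE_GROUPS, fractions=DEFAULT_AGE_FRACTIONS)


def synthetic_contact_matrix(n_groups: int, seed) -> np.ndarray:
    """Synthetic assortative age-contact matrix (survey stand-in).

    Strictly diagonally dominant row-wise with banded decay away from the
    diagonal, plus small positive seeded noise so it is asymmetric like a
    raw per-capita contact table.
    """
    if n_groups < 1:
        raise ValueError("need at least one age group")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_groups)
    band = 2.0 ** (-np.abs(idx[:, None] - idx[None, :]).astype(float))
    noise = rng.uniform(0.9, 1.1, size=(n_groups, n_groups))
    c = band * noise
    # enforce strict row-wise diagonal dominance
    off = c.sum(axis=1) - np.diag(c)
    np.fill_diagonal(c, np.maximum(np.diag(c), off * 1.05 + 0.1))
    return c


@dataclass(frozen=True)
class CityConfig:
    """One benchmark configuration; all fields have physical units noted."""

    N: int = 10_000
    radius_km: float = 2.5
    tile_side_km: float = 0.5
    spatial_density: str = "uniform"
    fitness_family: str = "lognormal"
    fitness_params: dict = field(default_factory=dict)
    target_mu: float = 25.0
    beta: float = 1.0
    age_fractions: tuple = DEFAULT_AGE_FRACTIONS
    age_groups: tuple = DEFAULT_AGE_GROUPS
    seed: int = 0

    def __post_init__(self):
        if self.spatial_density not in SPATIAL_DENSITIES:
            raise ValueError(f"unknown spatial density {self.spatial_density!r}")
        if self.fitness_family not in FITNESS_FAMILIES:
            raise ValueError(f"unknown fitness family {self.fitness_family!r}")
        if not 0 < self.target_mu < self.N - 1:
            raise ValueError("target mean degree must lie in (0, N-1)")

    def fitness_distribution(self) -> FitnessDistribution:
        return FitnessDistribution(self.fitness_family, dict(self.fitness_params))

    def with_size(self, N: int) -> "CityConfig":
        """Same configuration at a different population size."""
        return replace(self, N=N)


def paper_city_configs() -> list[CityConfig]:
    """The nine benchmark configurations: three spatial densities crossed
    with three fitness families, N=10,000 on a 2.5 km disk, mu=25, beta=1."""
    return [
        CityConfig(
            spatial_density=sd,
            fitness_family=ff,
            seed=1000 + 10 * i + j,
        )
        for i, sd in enumerate(SPATIAL_DENSITIES)
        for j, ff in enumerate(FITNESS_FAMILIES)
    ]


# descriptive alias
benchmark_city_configs = paper_city_configs


@dataclass(frozen=True)
class CityRealization:
    """Everything build_city produced, ready for solving and sampling."""

    config: CityConfig
    tessellation: Tessellation
    population: pd.DataFrame  # id, tile_id, age_group (+ block_id)
    mixing: SocialMixingMatrix
    part: BlockPartition
    block_tiles: np.ndarray
    block_ages: np.ndarray
    fitness: np.ndarray
    delta: MixingDensityMatrix
    constraints: ConstraintSet


def build_city(cfg: CityConfig) -> CityRealization:
    """Materialize a city configuration into model inputs.

    Tessellates the disk, samples the population, builds the social
    mixing matrix and normalized distances, assembles the mixing-density
    matrix over the *occupied* (tile, age) blocks (empty cells are
    dropped; singleton cells get no intra-block density), samples the
    fitness vector and assembles the expectation constraints with
    ``p = mu / (N - 1)``.
    """
    root = np.random.SeedSequence(cfg.seed)
    s_pop, s_fit, s_contact = root.spawn(3)

    tess = tessellate_disk(cfg.radius_km, cfg.tile_side_km)
    ages = AgeStructure(groups=cfg.age_groups, fractions=cfg.age_fractions)
    pop = sample_population(cfg.N, tess, cfg.spatial_density, ages, s_pop)

    contacts = synthetic_contact_matrix(len(ages.groups), s_contact)
    mixing = mixing_matrix_from_contacts(contacts, ages)
    dists = distance_matrix(tess)

    # occupied (tile, age) cells become blocks, in sorted cell order
    cells = pop[["tile_id", "age_group"]].drop_duplicates().sort_values(
        ["tile_id", "age_group"]
    )
    block_tiles = cells["tile_id"].to_numpy()
    block_ages = cells["age_group"].to_numpy()
    cell_to_block = {
        (t, g): b for b, (t, g) in enumerate(zip(block_tiles, block_ages))
    }
    assignment = np.array(
        [cell_to_block[(t, g)] for t, g in zip(pop["tile_id"], pop["age_group"])]
    )
    pop = pop.assign(block_id=assignment)
    part = BlockPartition(assignment=assignment, n=len(cell_to_block))

    delta = build_delta(
        dists,
        mixing,
        block_tiles,
        block_ages,
        cfg.beta,
        block_sizes=part.sizes,
    )
    fitness = cfg.fitness_distribution().sample(cfg.N, s_fit)
    p = density_from_mean_degree(cfg.target_mu, cfg.N)
    constraints = build_constraints(p, delta, fitness, part)
    return CityRealization(
        config=cfg,
        tessellation=tess,
        population=pop,
        mixing=mixing,
        part=part,
        block_tiles=block_tiles,
        block_ages=block_ages,
        fitness=fitness,
        delta=delta,
        constraints=constraints,
    )
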