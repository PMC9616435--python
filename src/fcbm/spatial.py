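"""Data-driven block structure for spatial social networks.

A territory is tessellated into square tiles of side ``l``; each
individual carries a tile of residence and an age group, and each
(tile, age-group) cell is one block.  The block-to-block mixing density
combines a gravity-style distance decay ``d^(-beta)`` between tiles with
an age-group social-mixing matrix ``S`` obtained from a raw contact
matrix by imposing reciprocity and normalizing:

    Delta_IJ  ∝  d_{t_I t_J}^(-beta) * s_{g_I g_J}

normalized over unordered block pairs, with the diagonal doubled so that
the ordered sum is exactly 2.  Inter-tile distances are Euclidean between
tile centers, divided by l/2 so that the within-tile distance is 1 —
half the distance between neighboring tiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .blocks import MixingDensityMatrix

__all__ = [
    "Tessellation",
    "AgeStructure",
    "SocialMixingMatrix",
    "tessellate_disk",
    "distance_matrix",
    "mixing_matrix_from_contacts",
    "build_delta",
    "sample_population",
    "SPATIAL_DENSITIES",
]

SPATIAL_DENSITIES = ("uniform", "radial_increasing", "radial_decreasing")


@dataclass(frozen=True)
class Tessellation:
    """Square-lattice tiles covering a disk of radius ``radius`` (km)."""

    centers: np.ndarray  # (T, 2) km
    side: float  # km
    radius: float  # km

    @property
    def n_tiles(self) -> int:
        return self.centers.shape[0]

    def center_distances(self) -> np.ndarray:
        """Radial distance of each tile center from the origin (km)."""
        return np.hypot(self.centers[:, 0], self.centers[:, 1])


@dataclass(frozen=True)
class AgeStructure:
    """Ordered age-group labels with population fractions summing to 1."""

    groups: tuple
    fractions: np.ndarray

    def __post_init__(self):
        fr = np.asarray(self.fractions, dtype=float)
        if len(self.groups) != fr.size:
            raise ValueError("one fraction per group required")
        if (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "fractions", fr)


@dataclass(frozen=True)
class SocialMixingMatrix:
    """Symmetric age-mixing weights, normalized over unordered pairs."""

    s: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if not np.allclose(s, s.T, rtol=0, atol=1e-12) or (s < 0).any():
            raise ValueError("mixing matrix must be symmetric non-negative")
        object.__setattr__(self, "s", s)


def tessellate_disk(R: float, l: float) -> Tessellation:
    """Square lattice of pitch ``l`` with the origin at a lattice corner;
    a tile is kept iff its center lies within distance ``R`` of the origin."""
    if not 0 < l <= R:
        raise ValueError("tile side must satisfy 0 < l <= R")
    m = int(np.ceil(R / l))
    coords = (np.arange(-m, m) + 0.5) * l
    xx, yy = np.meshgrid(coords, coords)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    keep = np.hypot(centers[:, 0], centers[:, 1]) <= R
    if not keep.any():
        raise ValueError("tessellation is empty")
    return Tessellation(centers=centers[keep], side=float(l), radius=float(R))


def distance_matrix(t: Tessellation) -> np.ndarray:
    """Normalized inter-tile distances: Euclidean center distance over
    ``l/2``; the within-tile distance is set to 1."""
    diff = t.centers[:, None, :] - t.centers[None, :, :]
    d = np.hypot(diff[..., 0], diff[..., 1]) / (t.side / 2.0)
    np.fill_diagonal(d, 1.0)
    return d


def mixing_matrix_from_contacts(
    c: np.ndarray, ages: AgeStructure
) -> SocialMixingMatrix:
    """Symmetrize a raw (possibly asymmetric) age-contact matrix.

    Total contacts are made reciprocal,
    ``s~_IJ = (c_IJ w_I + c_JI w_J) / 2`` with ``w`` the group fractions,
    then normalized so the unordered-pair sum is 1.  Any positive overall
    scale would be absorbed by the mixing-density normalization anyway;
    the unit sum just makes reported matrices comparable.
    """
    c = np.asarray(c, dtype=float)
    k = len(ages.groups)
    if c.shape != (k, k) or (c < 0).any():
        raise ValueError("contact matrix must be a non-negative |G|x|G| matrix")
    if not c.any():
        raise ValueError("contact matrix is identically zero")
    w = ages.fractions
    s = (c * w[:, None] + c.T * w[None, :]) / 2.0
    triu = np.triu_indices(k)
    s = s / s[triu].sum()
    return SocialMixingMatrix(s=s)


def build_delta(
    d: np.ndarray,
    s: SocialMixingMatrix,
    block_tiles: np.ndarray,
    block_ages: np.ndarray,
    beta: float,
    block_sizes: np.ndarray | None = None,
) -> MixingDensityMatrix:
    """Mixing-density matrix for (tile, age) blocks.

    Unordered weights ``w_IJ = d[t_I, t_J]^(-beta) * s[g_I, g_J]`` are
    normalized over ``I <= J``; the emitted ordered matrix doubles the
    diagonal (``Delta_II = 2 w_II``) so the ordered sum is exactly 2 —
    the unique convention compatible with intra-block link counts that
    count every edge twice.

    If ``block_sizes`` is given, each weight is additionally multiplied
    by the number of unordered vertex pairs the block pair offers
    (``N_I N_J`` across blocks, ``N_I (N_I - 1)/2`` within).  This makes
    the per-pair link probability — not the block-pair link count —
    proportional to ``s * d^(-beta)``, which is the phenomenological
    reading of the gravity model, and it keeps the expected link counts
    feasible for arbitrarily small blocks (a singleton block offers no
    intra pair and automatically receives zero intra density).  Without
    sizes, the weights are the raw tile/age densities, appropriate when
    blocks are balanced or notional.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    block_tiles = np.asarray(block_tiles, dtype=int)
    block_ages = np.asarray(block_ages, dtype=int)
    if block_tiles.shape != block_ages.shape:
        raise ValueError("block index maps must align")
    w = d[np.ix_(block_tiles, block_tiles)] ** (-beta) * s.s[
        np.ix_(block_ages, block_ages)
    ]
    if block_sizes is not None:
        sz = np.asarray(block_sizes, dtype=float)
        if sz.shape != block_tiles.shape:
            raise ValueError("block_sizes must align with the block maps")
        pairs = np.outer(sz, sz)
        np.fill_diagonal(pairs, sz * (sz - 1.0) / 2.0)
        w = w * pairs
    n = w.shape[0]
    triu = np.triu_indices(n)
    total = w[triu].sum()
    if total <= 0:
        raise ValueError("all mixing weights vanish")
    w = w / total
    delta = w.copy()
    delta[np.diag_indices_from(delta)] *= 2.0
    # exact renormalization guards accumulated floating error
    delta *= 2.0 / delta.sum()
    return MixingDensityMatrix(delta=delta)


def _density_weights(t: Tessellation, spatial_density: str) -> np.ndarray:
    r = t.center_distances() / t.radius
    if spatial_density == "uniform":
        return np.ones(t.n_tiles)
    if spatial_density == "radial_increasing":
        return 1.0 + r
    if spatial_density == "radial_decreasing":
        return 2.0 - r
    raise ValueError(f"unknown spatial density {spatial_density!r}")


def sample_population(
    N: int,
    t: Tessellation,
    spatial_density: str,
    ages: AgeStructure,
    seed,
) -> pd.DataFrame:
    """Sample per-individual (tile, age-group) attributes.

    Tiles are drawn with probability proportional to the chosen density
    evaluated at tile centers (``1``, ``1 + r/R`` or ``2 - r/R``); age
    groups are i.i.d. from the age fractions.  Returns a table with
    columns ``id``, ``tile_id``, ``age_group``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    rng = np.random.default_rng(seed)
    wt = _density_weights(t, spatial_density)
    tiles = rng.choice(t.n_tiles, size=N, p=wt / wt.sum())
    age_idx = rng.choice(len(ages.groups), size=N, p=ages.fractions)
    return pd.DataFrame(
        {
            "id": np.arange(N),
            "tile_id": tiles,
            "age_group": age_idx,
        }
    )
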