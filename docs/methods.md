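# Methods

## Model

The package implements a tunable-density, fitness-corrected block model:
the maximum-entropy distribution over simple undirected graphs on `N`
vertices, partitioned into `n` blocks, subject to soft (expectation)
constraints on (i) the number of links between every ordered block pair
and (ii) every vertex's degree.  Intra-block link counts `L_II` follow the
doubled-diagonal convention (each intra-block edge counted twice), which
makes `Σ_J K_IJ` the expected total degree of block `I` with no diagonal
special case; the same convention applies to pair counts
(`N_II = N_I(N_I−1)`) and to every matrix the package reads or writes.

The two constraint families are parameterized by a density `p ∈ (0,1)`, a
symmetric mixing-density matrix `Δ` with `Σ_{I,J} Δ_IJ = 2`, and a
strictly positive fitness vector `f`:

    K_IJ = p C(N,2) Δ_IJ
    k_i  = p C(N,2) (f_i / Σ_{u∈I_i} f_u) Σ_J Δ_{I_i J}

Because `Δ` sums to 2, the expected total degree is `p N(N−1)` regardless
of the partition, so `p = μ/(N−1)` tunes the network mean degree to `μ`.
The identity `Σ_J K_IJ = Σ_{i∈I} k_i` holds by construction and is
validated (relative tolerance 1e−9) whenever a constraint set is formed.
Fitness only enters through within-block shares, so the model is invariant
under positive rescaling of `f`.

Feasibility validation is strict: `k_i > N−1`, `K_IJ > N_IJ`, or a
positive intra-block density on a singleton block all raise errors rather
than warnings, since no distribution over simple graphs can satisfy such
expectations.  Note that these *necessary* conditions are not sufficient:
with extreme fitness skew a block's intra-link target can exceed what its
low-fitness members can absorb (`K_II ≤ 2 Σ_{i∈I} k_i − 2 max_{i∈I} k_i`
is also necessary).  Such configurations are reported as solver
non-convergence, never silently accepted.

## Exact solver

Entropy maximization factorizes the graph distribution over edges,
`p_ij = t_ij/(1+t_ij)` with `t_ij = x_i x_j y_{I_iJ_j}`, where `x` and `y`
are exponentiated Lagrange multipliers.  The package solves the defining
nonlinear system by coordinate-wise fixed-point iteration in the style
standard for maximum-entropy graph ensembles:

    x_i  ← k_i  / Σ_{j≠i} x_j y_{IJ}/(1 + x_i x_j y_{IJ})
    y_IJ ← K_IJ / Σ_{i∈I,j∈J,i≠j} x_i x_j/(1 + x_i x_j y_IJ)

Numerical choices:

* **Initialization** at the sparse closed form (exact in the `p → 0`
  limit), which typically converges in tens of iterations at the sizes the
  solver targets.
* **Damping**: if the residual fails to shrink by at least 5% in a sweep,
  updates are geometrically damped in log space (exponent shrinking from 1
  toward 0.25).  The iteration is otherwise undamped and fully
  deterministic; the `seed` argument exists only for interface symmetry.
* **Convergence** is declared when the largest constraint violation —
  absolute for targets below 1, relative above — falls below `tol`
  (default 1e−8); the iteration cap is 10,000 sweeps.  Non-convergence is
  reported in the `SolverReport`, never silent.
* **Gauge fixing**: the map `x_i → c_I x_i (i∈I)`, `y_IJ → y_IJ/(c_I c_J)`
  leaves every `p_ij` unchanged.  The gauge is renormalized every sweep
  (and on output) so that `Σ_{i∈I} x_i = Σ_{i∈I} k_i` per block; this
  prevents drift along the degenerate direction toward overflow and makes
  multipliers comparable across runs.
* **Degenerate constraints**: `k_i = 0` pins `x_i = 0`; `K_IJ = 0` pins
  `y_IJ = 0`.  Both are limits of the system and are excluded from
  iteration.

The solver stores a dense `N×N` probability matrix per sweep, so it is
meant for networks up to a few thousand vertices; the data-driven
generator at `N = 10^4` uses the sparse closed form, for which no
iteration is needed.

## Sparse closed form

For `p ≪ 1`, linearizing `p_ij ≈ x_i x_j y_IJ` gives `x_i = k_i` and
`y_IJ = K_IJ/(D_I D_J)` with `D_I = Σ_J K_IJ`, i.e.

    p_ij ≈ p C(N,2) (f_i/Σ_{u∈I} f_u)(f_j/Σ_{w∈J} f_w) Δ_IJ.

Two approximation errors are worth understanding, because they set what
convergence to the exact solution can and cannot be expected:

1. **Linearization error**, of order `t_ij` itself; it vanishes as
   `p → 0`.  On cross-block pairs it is the only error, and the deviation
   from the exact solution decreases monotonically with density (verified
   down to ~1e−10 at `p = 10⁻³`).
2. **Self-pair error**: the closed-form denominators use full block sums,
   dropping the `j ≠ i` exclusion.  This is an `O(1/N_I)` relative error
   on intra-block probabilities that is *independent of density* — the
   single-block uniform case makes it exact: the closed form gives
   `p(N−1)/N` against the exact value `p` at every density.  The maximum
   deviation over all pairs is therefore pinned at `1/min_I N_I` rather
   than decreasing with density.  With heterogeneous fitness an analogous
   density-independent term `O(max_i k_i/D_I)` appears on cross-block
   pairs as well, because `x_i = k_i` does not solve the per-vertex
   equations exactly.

Products `x_i x_j y_IJ` can exceed 1 under heavy-tailed fitness; emitted
probabilities are clipped at 1 and the number of clipped pairs is counted
and exposed (`clipped_pairs`), along with the largest raw product, as
sparsity diagnostics.  No quantitative "sparse enough" cutoff is imposed;
the diagnostics let the user judge.  Clipping slightly depresses realized
mean degrees (≈0.3–0.5% at the benchmark configuration).

## Degree-distribution estimators

If fitness values are i.i.d. from `p_f` with analytic mean `⟨f⟩`, the
sparse model gives a vertex of fitness `f` in block `I` the expected
degree `k(f,I) ≈ f μ_I/⟨f⟩`, where `μ_I = D_I/N_I` is the block's expected
mean degree.  Inverting this change of variables yields two estimates of
the network degree density:

* block-resolved: `p_k(k) = (⟨f⟩/N) Σ_I p_f(k⟨f⟩/μ_I) N_I/μ_I`
* global: `p_k(k) = p_f(k⟨f⟩/μ) ⟨f⟩/μ`, with `μ` the network mean degree.

Both inherit the shape of `p_f`: exponential fitness gives exactly
`e^{−k/μ}/μ` (any rate), Pareto fitness a `k^{−a−1}` tail, lognormal
fitness a lognormal with the same log-sd.  Blocks with `μ_I = 0`
contribute a point mass `N_I/N` at degree 0 (the limit of the change of
variables).

Empirical degrees are integers, so for comparisons the estimator densities
are evaluated on the integer grid and renormalized there; the
Kolmogorov–Smirnov distance is then the max absolute difference of the
discrete CDFs, with the grid extended until the estimator's tail mass is
below 1e−12.  Because the closed forms are least reliable at very small
degrees, `ks_distance` optionally restricts both distributions to
`k ≥ min_degree` and renormalizes.

**Validity regime.**  The derivation replaces the within-block fitness sum
`Σ_{u∈I} f_u` by `⟨f⟩N_I`, an approximation that needs reasonably
populated blocks.  At the benchmark scale (`N = 10,000`, 400 tile×age
cells, mean occupancy 25) the block-resolved estimate tracks 10-instance
averaged degree histograms with KS ≈ 0.014–0.050 across all nine
density×fitness configurations and beats the global estimate everywhere.
At `N = 3,000` (occupancy 7.5) the finite-block fluctuation of the fitness
shares dominates: measured KS rises to 0.036–0.059 and the global
estimate — whose single scale happens to be less sensitive to the
within-block compression of extreme fitness shares — can come out ahead.
Diagnostically, the block-resolved estimator still matches the idealized
`k(f,I)` Poisson mixture to KS ≤ 0.005 there; the gap is entirely the
small-block effect.  Tests of estimator agreement therefore run at the
benchmark size, which is the regime the estimators are built for.

## Data-driven spatial construction

* **Tessellation**: square lattice of pitch `l` with the origin at a
  lattice corner; tiles kept iff the center lies within the disk radius.
  A 2.5 km disk with `l = 0.5` km gives 80 tiles.
* **Distances**: Euclidean between tile centers, divided by `l/2`, so
  adjacent tiles sit at distance 2 and the within-tile distance is set to
  1 — half the neighbour distance.  (Tile centers, not boundary or
  population-weighted points, are the representative points.)
* **Age mixing**: a raw, possibly asymmetric contact-rate matrix `c` is
  made reciprocal with the group fractions `w` as
  `s̃_IJ = (c_IJ w_I + c_JI w_J)/2` and normalized to unit sum over
  unordered group pairs.  The overall scale of `S` is irrelevant (the
  mixing-density normalization absorbs it); the unit sum is fixed only so
  reported matrices are comparable.
* **Mixing densities**: unordered block-pair weights
  `w_IJ = n_IJ · d_{t_It_J}^{−β} · s̃_{g_Ig_J}` are normalized to unit sum
  over `I ≤ J` and emitted with the doubled diagonal, making the ordered
  sum exactly 2.  Here `n_IJ` is the number of unordered vertex pairs the
  block pair offers (`N_I N_J` across, `N_I(N_I−1)/2` within).  The
  pair-count factor makes the *per-pair* link probability — not the
  block-pair link count — proportional to `s̃ d^{−β}`, which is the
  phenomenological gravity reading (with uniform fitness the fitness
  shares contribute exactly `1/(N_I N_J)`, cancelling it), and it keeps
  expected link counts feasible for arbitrarily small blocks: a singleton
  block offers no intra pair and automatically receives zero intra-block
  density.  Without the factor, every block pair would carry equal
  expected link counts regardless of population, which drives `K_II` above
  `N_II` for small cells and is rejected by validation.  `build_delta`
  also accepts no sizes, in which case the raw tile/age weights are used —
  appropriate for notional or balanced blocks.
* **Population sampling**: tiles are drawn with probability proportional
  to a density evaluated at tile centers — uniform, `1 + r/R` (radially
  increasing) or `2 − r/R` (radially decreasing); the two radial forms are
  the simplest monotone families and are configurable.  Age groups are
  i.i.d. from the age fractions.  Only occupied tile×age cells become
  blocks.

## Stylized-city benchmark

The benchmark emulates an idealized urban area with no external data:
`N = 10,000` inhabitants on a 2.5 km disk, 0.5 km tiles, `β = 1`, density
tuned for mean degree `μ = 25`, three spatial densities × three fitness
families (nine configurations).  Synthetic stand-ins replace survey and
census inputs:

* age pyramid: five bands with fractions (0.15, 0.20, 0.25, 0.25, 0.15) —
  a generic, configurable placeholder;
* contact matrix: banded decay `2^{−|i−j|}` with seeded multiplicative
  noise and the diagonal raised to strict row dominance — assortative like
  empirical age-contact tables, reproducible by seed;
* fitness defaults: Pareto(shape 2.5, scale 1), lognormal(0, 1),
  exponential(rate 1).  By the change-of-variables result the degree
  *shape* depends on `p_f` only through its family shape, so these
  defaults do not condition the benchmark conclusions; all are
  configurable.

All stochastic stages derive their streams from a single root seed
(`SeedSequence.spawn`), so every artifact is reproducible from the
configuration alone; ensembles give each graph an independent child
stream.

## Problem sizes used in tests

The exact solver is exercised at `N ≤ 60` (with an exhaustive 2^10-graph
enumeration oracle at `N = 5` and a 20,000-draw Monte-Carlo oracle at
`N = 6`); estimator-agreement checks run the nine benchmark configurations
at the full `N = 10,000` with 10 instances each; sampler moment checks use
`N = 500` with 200 seeds.  These sizes were chosen so the whole suite
completes in a few minutes while each check stays in the regime it is
scientifically meant for.

## Known limitations

* The sparse closed form (and everything downstream: the data-driven
  generator at scale, the degree estimators) carries the density-
  independent `O(1/N_I)` self-pair deviation described above; for
  networks with very small blocks, solve the exact system instead.
* The degree estimators assume well-populated blocks; below ~10 residents
  per block their accuracy degrades as quantified above.
* Simple undirected graphs only; no overlapping blocks, no weighted or
  directed variants, no temporal dynamics.
* Sampling is `O(N²)` Bernoulli trials (chunked, vectorized); `N = 10^4`
  takes ~1.5 s per graph, but much larger populations would want a
  sparsity-exploiting sampler, which is out of scope.
* The synthetic city is a stand-in: real survey contact matrices, census
  age pyramids and map-based tessellations have structure (household
  clustering, commuting flows, irregular tile occupancy) the generator
  does not emulate, so benchmark agreement does not certify performance
  on real data inputs.
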