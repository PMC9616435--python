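# fcbm — fitness-corrected block models for synthetic spatial social networks

`fcbm` generates maximum-entropy random graphs for age- and
geography-stratified populations.  It is aimed at epidemiological and
computational-social-science modellers who need synthetic contact networks
that honour block-level mixing data (who-meets-whom by age group and
location) and individual-level heterogeneity (some people simply have more
contacts), while being otherwise maximally random — so that no unintended
structure leaks into downstream simulations.

## The model

Vertices `0..N-1` are partitioned into `n` blocks (here: residence tile ×
age group).  Given a density `p ∈ (0,1)`, a symmetric mixing-density matrix
`Δ` with ordered-pair sum `Σ_{I,J} Δ_IJ = 2`, and a positive fitness vector
`f`, the model is the maximum-entropy distribution over simple graphs with

    ⟨L_IJ⟩ = p C(N,2) Δ_IJ                                   (block-pair link counts)
    ⟨deg_i⟩ = p C(N,2) (f_i / Σ_{u∈I_i} f_u) Σ_J Δ_{I_i J}   (expected degrees)

where `L_II` counts intra-block edges twice.  Entropy maximization
factorizes the distribution over edges:

    p_ij = x_i x_j y_{I_i J_j} / (1 + x_i x_j y_{I_i J_j}),

with exponentiated Lagrange multipliers `x_i`, `y_IJ` solving the nonlinear
system above (`fcbm.solve_fcbm`; `fcbm.solve_dcbm` takes measured `K`, `k`
from an observed graph instead).  In the sparse regime `p ≪ 1` the system
has the closed-form solution `x_i = k_i`, `y_IJ = K_IJ / (D_I D_J)` with
`D_I` the expected block degree total, giving

    p_ij ≈ p C(N,2) (f_i/Σ_{u∈I} f_u) (f_j/Σ_{w∈J} f_w) Δ_IJ,

and the network degree density inherits the *shape* of the fitness
distribution: `p_k(k) ≈ p_f(k⟨f⟩/μ) ⟨f⟩/μ` globally, or the more accurate
block-resolved mixture `p_k(k) ≈ (⟨f⟩/N) Σ_I p_f(k⟨f⟩/μ_I) N_I/μ_I`
(`fcbm.degree_pdf_global`, `fcbm.degree_pdf_blockwise`).

For spatial networks, `Δ` is built from data: an age-mixing matrix `S`
(raw contact rates symmetrized by reciprocity) and a gravity-style distance
decay `d_IJ^{-β}` between tiles, with within-tile distance normalized to
half the neighbouring-tile distance.  A fully synthetic "stylized city"
(disk of radius 2.5 km, 0.5 km square tiles, five age bands, assortative
contact matrix) provides a self-contained benchmark.

## Worked example

```python
import numpy as np
import fcbm

cfg = fcbm.CityConfig(
    N=2000, spatial_density="radial_decreasing", fitness_family="lognormal",
    target_mu=25.0, seed=42,
)
city = fcbm.build_city(cfg)
print(f"blocks: {city.part.n}")
print(f"delta ordered sum: {city.delta.delta.sum():.15f}")

model = fcbm.sparse_multipliers_fcbm(city.constraints, city.part)
print(f"pairs clipped at probability 1: {model.clipped_pairs()}")

graphs = fcbm.sample_ensemble(model, 10, seed=7)
mean_deg = np.mean([2 * g.number_of_edges() / cfg.N for g in graphs])
print(f"ensemble mean degree: {mean_deg:.2f} (target 25.0)")

pmf = fcbm.empirical_degree_distribution(graphs)
fd = cfg.fitness_distribution()
mus = fcbm.block_mean_degrees(city.constraints, city.part)
ks_block = fcbm.ks_distance(pmf, fcbm.degree_pdf_blockwise(fd, mus, city.part))
ks_global = fcbm.ks_distance(pmf, fcbm.degree_pdf_global(fd, cfg.target_mu))
print(f"KS vs block-resolved estimate: {ks_block:.3f}")
print(f"KS vs single-scale estimate:   {ks_global:.3f}")
```

prints

```
blocks: 390
delta ordered sum: 2.000000000000000
pairs clipped at probability 1: 255
ensemble mean degree: 24.58 (target 25.0)
KS vs block-resolved estimate: 0.054
KS vs single-scale estimate:   0.032
```

The 2,000 residents occupy 390 of the 400 tile×age cells; the mixing
densities are normalized exactly; the density parameter `p = μ/(N−1)`
delivers the requested mean degree up to the small loss from clipping
heavy-tailed edge probabilities at 1.  The Kolmogorov–Smirnov distances
compare the sampled degree histogram with the two analytic estimates.  At
this deliberately small population the blocks average only ~5 residents,
below the large-block regime the estimators assume, so the block-resolved
estimate loses its usual advantage; at the benchmark size `N = 10,000`
(mean occupancy 25) it is the tighter of the two — see
`docs/methods.md`.

A YAML-driven command line wraps the same pipeline:

```
fcbm run --config config.yaml --out results/
fcbm city | solve | sample | degrees | report   # stage by stage
```

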