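# riverpopgen

Population genetics of metapopulations living on dendritic river networks.

Riverine landscapes constrain organisms to a branching, flow-directed
network: dispersal follows channels, often with a downstream bias, and
habitat capacity grows with stream size. `riverpopgen` bundles the pieces
needed to study how that spatial structure shapes neutral genetic
diversity — and to confront a mechanistic simulation with field data on the
*same* network:

- **`network`** — a validated river-network data model (an in-tree of
  subcatchment nodes with instream edge lengths) and the node connectivity
  metrics used as predictors: upstream distance to the outlet, accumulated
  catchment area, directed/undirected betweenness and closeness
  centralities (closeness min–max standardized to [0, 1]), degree, and
  instream (along-network) distance matrices.
- **`popgen`** — a diploid microsatellite genotype table and the classical
  statistics: rarefied allelic richness
  `AR_g = Σ_a [1 − C(N−N_a, g)/C(N, g)]`, observed heterozygosity `Ho`,
  unbiased gene diversity `Hs = n/(n−1)(1 − Σp² − Ho/2n)`,
  `F_IS = 1 − Ho/Hs`, pairwise Nei `F_ST = (Ht − Hs)/Ht` (loci averaged
  before the ratio, with Nei's sample-size corrections), the
  Garza–Williamson M-ratio `M = k/(r+1)`, and a permutation Mantel test.
- **`simulator`** — a discrete-time, individual-based metapopulation model:
  diploid, sexual (sex ratio 0.5), non-overlapping generations with
  Beverton–Holt density regulation (per-female mean offspring
  `2λ₀ / (1 + (λ₀−1) N_i/K_i)`), ten neutral loci with 100 allele states
  under stepwise (±1, reflecting) or random (uniform) mutation at rate μ,
  and natal nearest-neighbour dispersal at rate `d` with downstream weight
  1 and upstream weight `W` per neighbour. Capacities are uniform or scale
  with the square root of accumulated catchment area at constant
  metapopulation size.
- **`modelfit`** — goodness of fit of simulated versus empirical node
  statistics by perpendicular offsets from the 1:1 line
  (`(sim − emp)/√2`): the sum (SPO), median of absolute values (MPO) and
  signed median (DMPO), plus parameter-wise win fractions over a scenario
  grid (a parameter value "wins" a context when its measure is strictly
  smaller).
- **`regression`** — OLS with a pinned Gaussian AIC/AICc convention,
  Kendall-τ collinearity screening, backward stepwise and all-subsets
  (dredge-style) selection, variance-inflation factors, and the
  isolation-by-distance power scan: `F_ST ~ distance^p (× species)` over
  p = 0…1 in steps of 0.01, selecting the minimum-AIC exponent.
- **`synthetic`** — random dendritic networks and Balding–Nichols
  island-model genotypes with a calibrated target pairwise F_ST, so every
  estimator has a quantitative oracle without field data.
- **`workflows`** — end-to-end recipes (site-diversity summary, scenario
  grids, fit studies) composing the above.

The package is used from Python; `examples/` holds one narrative script per
capability. A thin `riverpopgen` CLI (`netstats`, `popgen`, `simulate`,
`fit`, `regress`, `synth`) covers shell-driven batch runs.

## Worked example

```python
import numpy as np
from riverpopgen.popgen import node_diversity, pairwise_nei_fst
from riverpopgen.synthetic import SyntheticGenotypeConfig, island_model_genotypes

gt = island_model_genotypes(
    SyntheticGenotypeConfig(n_pops=6, n_per_pop=40, n_loci=9,
                            target_fst=0.15, seed=11)
)
div = node_diversity(gt)          # n, g, AR, Ho, He, Fis per population
fst = pairwise_nei_fst(gt)        # symmetric Nei F_ST matrix
vals = fst.to_numpy()[np.triu_indices(len(fst), 1)]
print(round(float(np.nanmean(vals)), 3))
```

prints `0.153`: six island populations generated at a target pairwise
differentiation of 0.15 are estimated at 0.153 by the Nei F_ST estimator —
generator and estimator agree to sampling noise. Running
`python examples/simulate_metapopulation.py` likewise shows per-replicate
Spearman correlations of −0.55 … −0.36 between allelic richness and
upstream distance: with downstream-only dispersal, genetic diversity
accumulates toward the outlet.

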