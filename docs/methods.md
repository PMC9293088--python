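# Methods

This note records the models, estimator conventions and numerical choices
implemented in `riverpopgen`, and what the synthetic test systems do and do
not show about real data.

## River-network model

A river network is a directed in-tree: nodes are subcatchments, each
non-outlet node has exactly one downstream edge, and edge weights are
instream lengths in km between subcatchment outlets. Node attributes carry
the local subcatchment area (km²); accumulated catchment area is the sum of
local areas over the upstream subtree. Validation rejects cycles, multiple
outlets, nodes with two downstream edges and non-positive lengths, each
with a named error.

Metric conventions (the directed variants of graph centralities depend on
conventions that differ between libraries, so ours are pinned):

- Edges are stored upstream → downstream and "directed" metrics follow this
  flow orientation (directed reachability = "can drift downstream to").
- All shortest-path computations are weighted by edge length.
- Betweenness is reported as raw path counts (unnormalized); the regression
  layer log-transforms it, so only monotone scale matters, but the scale is
  fixed here once.
- Closeness is `1/Σ_j d(i, j)`. In directed mode, unreachable ordered pairs
  are excluded from the sum; on an in-tree most ordered pairs are mutually
  unreachable and an infinite-distance convention would zero every value.
  A node reaching nothing gets closeness 0. Standardized closeness is
  `(c_i − min c)/(max c − min c)`; an all-equal vector raises a
  degenerate-spread error rather than dividing by zero.
- Instream distance between nodes i and j is
  `up(i) + up(j) − 2·up(lca(i, j))` with `up` the distance to the outlet
  and `lca` the deepest shared node of the two downstream paths; this
  equals the unique undirected tree-path distance.

## Genetic statistics

Genotypes are diploid integer allele states (microsatellite fragment sizes
or simulator labels), with per-locus calls either fully observed or fully
missing; missing data are handled by per-locus pairwise deletion, and loci
enter node means only where defined.

- **Allelic richness** is rarefied by the hypergeometric expectation
  `AR_g = Σ_a [1 − C(N−N_a, g)/C(N, g)]` (computed via log-gamma for
  stability; exact for small N). The default g is the rarefy-to-minimum
  convention: twice the smallest number of fully observed individuals over
  all (node, locus) cells of the table at hand. Empirical workflows apply
  this per species; g is always reported next to AR.
- **Expected heterozygosity** defaults to the unbiased estimator
  `Hs = n/(n−1) (1 − Σp² − Ho/2n)`; the plain gene diversity `1 − Σp²` is
  available by flag. The choice is pinned because multi-site means are only
  comparable under a stated estimator.
- **F_IS** is `1 − mean(Ho)/mean(Hs)` with means over loci taken before the
  ratio.
- **Pairwise Nei F_ST**: per locus and population pair, `Hs` is the mean
  unbiased within-population gene diversity (with the harmonic mean sample
  size), and `Ht = 1 − Σ p̄² + Hs/(ñ·np) − Ho/(2ñ·np)` from unweighted mean
  allele frequencies; `Hs` and `Ht` are averaged over loci *before* the
  ratio `(Ht − Hs)/Ht` — the standard Nei (1987) practice. Loci observed in
  only one member of a pair are excluded from that pair; a pair with
  `Ht = 0` is undefined (NaN). Small negative estimates are reported as
  computed; zeroing is deliberately deferred to the isolation-by-distance
  model, which is the one place the artefact matters.
- **M-ratio** `M = k/(r+1)` treats the integer allele states as sizes on a
  1-unit repeat ladder; monomorphic loci give M = 1 by convention.
- **Mantel test**: Pearson correlation of upper-triangle entries; the
  one-tailed p-value permutes rows and columns of the second matrix jointly
  and uses add-one smoothing `(b+1)/(n_perm+1)`. The seed is mandatory.

## Individual-based simulator

Life cycle per generation: **reproduction → mutation → natal dispersal →
census**, with non-overlapping generations. Each female with at least one
local male draws a uniform-random local father (with replacement; a male
can sire several broods) and produces a Poisson number of offspring with
mean `2λ₀ / (1 + (λ₀−1) N_i/K_i)` — a Beverton–Holt form whose female-based
factor 2 compensates the 0.5 sex ratio so the equilibrium sits at K_i. N_i
counts all adults of both sexes at the start of reproduction. Offspring
inherit one uniformly chosen allele per locus from each parent and a sex
with probability 0.5.

Defaults mirror the study conditions the package emulates: mean carrying
capacity K = 1000 per node, μ = 10⁻⁴ per allele copy per generation,
λ₀ = 2, no dispersal mortality, ten unlinked loci, 100 allele states,
10,000 generations, ten replicates.

- **Allele states** are labelled 1…100 with reflecting stepwise boundaries
  (from 1 always to 2, from 100 always to 99). A ladder of exactly 100
  states was chosen where "reflecting at the ends of a 100-value ladder"
  could also be read as 101 labels; the state count, not the labels, is
  what matters for diversity.
- **Random mutation** resamples uniformly over all 100 states including the
  current one, so the effective change probability is μ(1 − 1/100).
- **Dispersal** moves each offspring with probability d to an adjacent
  node drawn with weight 1 for the downstream neighbour and W for each
  upstream neighbour, normalized; if all weights are zero (the outlet with
  W = 0) the individual stays. Dispersal mortality m removes migrants in
  transit (default 0).
- **Capacity scaling** (`k_mode="scaled"`) sets `K_i ∝ √A_i` with A_i the
  accumulated catchment area, normalized to keep `Σ K_i = n_nodes·K_base`
  and floored at 2; the outlet, accumulating the whole basin, gets the
  maximum.
- **Initialization** seeds every node at capacity with uniform-random
  alleles and sexes: runs of several thousand generations reach
  quasi-equilibrium regardless of the start, and the uniform start
  converges fastest.
- **Reproducibility**: one master seed; per-replicate streams come from
  `SeedSequence.spawn`, so identical (params, seed) reruns are bit
  identical and replicates are independent.

## Model–data fit

Points (empirical, simulated) per node are scored by the signed
perpendicular distance to the 1:1 line, `(sim − emp)/√2`. SPO (sum of
absolute offsets) measures overall spread, MPO (median absolute offset) is
robust to outlier nodes, DMPO (median signed offset) gives the direction of
mis-fit. Simulated statistics are replicate means per node, computed with
the same estimators as the empirical side; by default simulated nodes are
subsampled to the empirical per-node sample sizes and rarefied to a shared
g (harmonized to the smallest observed cell across all tables, capped),
because AR is strongly sample-size dependent. Win fractions compare every
pair of scenarios differing only in the tested parameter, across contexts =
other-parameter combinations × responses × species × {SPO, MPO}; a win
requires a strictly smaller measure, exact ties count for neither side and
are reported separately. For the 3×3×2 grid with 3 responses and 2 species
this gives 144 comparisons for the three-valued parameters and 108 for the
capacity mode.

## Regression layer

OLS on term-structured designs (terms are products of predictor columns;
two-level categoricals are treatment-coded). Information criteria use the
full Gaussian form `AIC = n ln(2π RSS/n) + n + 2(k+1)` and
`AICc = AIC + 2(k+1)(k+2)/(n−k−2)`, counting the residual variance as a
parameter; the convention only shifts all models by a constant and is
pinned so printed values are comparable across operations. Customary
transforms: natural log for accumulated catchment area and `log(x+1)` for
directed betweenness, whose leaves are exactly 0. The Kendall screen drops,
among pairs with |τ| above the threshold (default 0.8), the member with
the larger mean |τ| against all remaining predictors, iterating until no
pair offends — the tie-break is ours, chosen to remove the most redundant
column first. Backward stepwise respects marginality (main effects leave
only after their interactions). The isolation-by-distance scan fits
`F_ST ~ distance^p × species` for p = 0, 0.01, …, 1 and selects the
minimum-AIC exponent; p = 0 drops the then-constant distance term, and
negative F_ST estimates are set to zero before fitting.

## Synthetic test systems

The network generator grows a random recursive in-tree (lognormal edge
lengths ≈ 1–3 km, gamma local areas with mean 2 km², a branching-bias
parameter for attaching to leaves versus interior nodes), emulating a
fine-grained subcatchment representation. The genotype generator draws
population allele frequencies from a Balding–Nichols Dirichlet around
shared ancestral frequencies. Because the estimators measure *pairwise*
differentiation, the generator calibrates analytically: islands at
Balding–Nichols divergence F have expected pairwise Nei F_ST of F/(2−F)
(each pair is referenced to its own mean frequencies), so a target t is
generated at F = 2t/(1+t). Per-node sample sizes default to 15–40
individuals, matching field practice above a 15-individual inclusion
filter.

What the synthetic systems do *not* contain: spatially autocorrelated
allele frequencies, realistic channel geomorphology, null alleles or
genotyping error, demographic history (bottlenecks, expansions), or
selection. Passing tests therefore validate the estimators, the simulator
mechanics and the fit framework — not any claim about a particular field
system.

## Problem sizes and limitations

Tests and the acceptance script run the simulator at reduced scale — 20-node
networks, K = 100 per node, hundreds to a few thousand generations, 2–10
replicates — sizes chosen so each qualitative property (demographic
equilibrium, fixation under pure drift, the downstream diversity gradient,
direction-of-effect in the scenario comparison) is already unambiguous.
Full-scale studies (thousands of nodes, K = 1000, 10⁴ generations, ten
replicates, the complete 36-scenario grid) use the same code paths and
scale linearly in individuals × generations. The scenario-comparison
recipes sample "field sites" only at nodes whose scaled capacity supports
sampling (≥ 40 individuals here), mirroring the fact that field designs
avoid sites too small to yield the minimum sample; without this, rarefaction
to a common g would be driven by the single smallest headwater under
capacity scaling.

Known limitations: the directed-closeness convention is one of several
defensible choices and must match when comparing against other software;
F_ST between populations with no shared polymorphic loci is undefined
rather than 0; the simulator assumes strict generational synchrony and no
overlapping generations; and the Kendall-screen tie-break can differ from
other implementations when several pairs exceed the threshold
simultaneously.
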