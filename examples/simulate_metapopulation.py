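"""Individual-based metapopulation simulation on a river network.

Runs the neutral simulator (Beverton-Holt regulation, stepwise mutation,
downstream-only natal dispersal) on a 20-node synthetic network and shows
the classic spatial signature: allelic richness increases downstream
(negative correlation with upstream distance) when movement follows flow.
"""

from scipy.stats import spearmanr

from riverpopgen.network import upstream_distances
from riverpopgen.popgen import allelic_richness
from riverpopgen.simulator import SimulationParams, run
from riverpopgen.synthetic import SyntheticNetworkConfig, random_dendritic_network

net = random_dendritic_network(SyntheticNetworkConfig(n_nodes=20, seed=7))
params = SimulationParams(
    d=0.01, W=0.0, k_mode="fixed", K_base=100,
    generations=1000, replicates=3, seed=42,
)
results = run(net, params, record_every=250)

print("trajectory of replicate 0 (total N and mean expected heterozygosity):")
print(results[0].trajectory.round(3).to_string(index=False))

up = upstream_distances(net)
print("\nallelic richness vs upstream distance per replicate:")
for res in results:
    ar, g = allelic_richness(res.genotypes, g=40)
    ar = ar.reset_index()
    rho = spearmanr([up[n] for n in ar["node_id"]], ar["AR"]).statistic
    print(f"  replicate {res.replicate}: Spearman rho = {rho:.3f} (g = {g})")
print(
    "\nNegative correlations mean diversity accumulates toward the outlet "
    "— the downstream increase in intraspecific genetic diversity expected "
    "under drift with flow-directed dispersal."
)
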