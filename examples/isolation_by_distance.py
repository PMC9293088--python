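"""Isolation by distance: Mantel test and the power-term scan.

Simulates a metapopulation on a river network, computes pairwise Nei F_ST
and instream distances, and (1) tests their association with a Mantel
permutation test, (2) scans the exponent p of the saturating model
F_ST ~ distance^p for the minimum-AIC fit.
"""

import numpy as np

from riverpopgen.network import instream_distance_matrix
from riverpopgen.popgen import fst_long, mantel_test, pairwise_nei_fst
from riverpopgen.regression import power_scan
from riverpopgen.simulator import SimulationParams, run
from riverpopgen.synthetic import SyntheticNetworkConfig, random_dendritic_network

net = random_dendritic_network(SyntheticNetworkConfig(n_nodes=18, seed=3))
params = SimulationParams(
    d=0.01, W=0.5, K_base=100, generations=1500, replicates=1, seed=8
)
res = run(net, params, record_every=1500)[0]

fst = pairwise_nei_fst(res.genotypes, species=params.scenario_label())
dmat = instream_distance_matrix(net, list(fst.index))
r, p = mantel_test(dmat.to_numpy(), np.nan_to_num(fst.to_numpy()),
                   n_perm=999, seed=1)
print(f"Mantel test: r = {r:.3f}, one-tailed p = {p:.4f}")

pairs = fst_long(fst).dropna(subset=["fst"])
dist = np.array([dmat.loc[a, b] for a, b in zip(pairs.node_a, pairs.node_b)])
best_p, fit, curve = power_scan(pairs["fst"].to_numpy(), dist)
print(f"power scan: best exponent p = {best_p:.2f} "
      f"(AIC = {fit.aic:.1f}, R2_adj = {fit.r2_adj:.3f})")
print(
    "\nA positive Mantel r confirms that genetic differentiation grows "
    "with instream distance; an exponent below 1 captures the saturating "
    "shape of that increase."
)
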