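"""Scenario-grid goodness of fit with perpendicular offsets.

Samples reference ("pseudo-empirical") genotypes from a truth simulation
with no upstream movement (W = 0), re-runs a small scenario grid on the
same network, scores every scenario against the reference by the sum and
median of perpendicular offsets from the 1:1 line, and reports which
parameter values win the majority of pairwise comparisons.
"""

from riverpopgen import workflows as wf
from riverpopgen.popgen import GenotypeTable, node_diversity, subsample
from riverpopgen.simulator import SimulationParams, run, scaled_capacities
from riverpopgen.synthetic import SyntheticNetworkConfig, random_dendritic_network

net = random_dendritic_network(SyntheticNetworkConfig(n_nodes=20, seed=101))
sc = scaled_capacities(net, 100)
sites = [n for n in net.nodes if sc[n] >= 40]  # sampleable under either K mode

truth = SimulationParams(d=0.01, W=0.0, k_mode="fixed", K_base=100,
                         generations=400, replicates=1, seed=9999)
res = run(net, truth, record_every=400)[0]
gt = res.genotypes
gt = GenotypeTable(
    gt.data[gt.data["node_id"].isin(set(sites))].reset_index(drop=True),
    loci=gt.loci,
)
emp_gt = subsample(gt, 15, seed=5)  # field-like sampling: 15 per site

base = SimulationParams(K_base=100, generations=400, replicates=2, seed=1)
scenarios = wf.scenario_grid(base)  # 3 d x 3 W x 2 K modes = 18 scenarios
sim_stats, g = wf.run_scenario_grid(
    net, scenarios, node_subset=sites, sample_sizes={n: 15 for n in sites},
    extra_tables=[emp_gt], seed=7,
)
emp = node_diversity(emp_gt, g=g).reset_index()
emp["species"] = "A"
study = wf.fit_study(emp[["node_id", "species", "AR", "Ho", "He"]], sim_stats)

print("parameter-wise win fractions (wins / pairwise comparisons):")
print(study["comparisons"].round(3).to_string(index=False))
print(
    "\nThe reference data were generated with W = 0 (no upstream movement), "
    "d = 0.01 and uniform capacities; win fractions above 0.5 mean the "
    "fit framework recovers those generating conditions."
)
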