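"""Microsatellite diversity and differentiation statistics.

Generates island-model genotypes with a known target differentiation
(F_ST = 0.15), then computes per-population rarefied allelic richness,
observed/expected heterozygosity, F_IS and the pairwise Nei F_ST matrix —
the estimator should recover the configured target.
"""

import numpy as np

from riverpopgen.popgen import node_diversity, pairwise_nei_fst
from riverpopgen.synthetic import SyntheticGenotypeConfig, island_model_genotypes

gt = island_model_genotypes(
    SyntheticGenotypeConfig(
        n_pops=6, n_per_pop=40, n_loci=9, target_fst=0.15, seed=11
    )
)
div = node_diversity(gt)
print("per-population diversity (AR rarefied to g gene copies):")
print(div.round(3).to_string())

fst = pairwise_nei_fst(gt)
vals = fst.to_numpy()[np.triu_indices(len(fst), 1)]
print("\npairwise Nei F_ST:")
print(fst.round(3).to_string())
print(
    f"\nmean pairwise F_ST = {np.nanmean(vals):.3f} "
    "(the generator was configured for 0.15; agreement shows the Nei "
    "estimator and the island-model calibration are consistent)"
)
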