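"""Synthetic dendritic networks and structured genotype data.

These generators make every analysis layer testable without field data:

* :func:`random_dendritic_network` grows a random in-tree one headwater at a
  time, mimicking a subcatchment representation of a river basin (edge
  lengths lognormal around a few km, local areas gamma around 2 km^2).
* :func:`island_model_genotypes` draws population allele frequencies from a
  Balding-Nichols Dirichlet around shared ancestral frequencies, giving an
  island model with a known expected F_ST — a quantitative oracle for the
  differentiation estimators.  Individuals are sampled in Hardy-Weinberg
  proportions within populations.
* :func:`write_worked_fixture` writes the small worked examples (a 7-node
  binary-tree network, a 4-individual genotype table) used in tests and
  docs, byte-stable under reruns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import RiverNetwork
from .popgen import GenotypeTable

__all__ = [
    "SyntheticNetworkConfig",
    "SyntheticGenotypeConfig",
    "random_dendritic_network",
    "island_model_genotypes",
    "write_worked_fixture",
]


@dataclass(frozen=True)
class SyntheticNetworkConfig:
    """Random dendritic-network settings.

    Edge lengths ~ lognormal(log km), local areas ~ gamma(km^2, mean
    shape*scale = 2 km^2 by default, mirroring a ~2 km^2 subcatchment
    resolution), ``leaf_attach_prob`` is the probability a new headwater
    attaches upstream of a current leaf rather than of a random node
    (higher values give longer, less branched channels).
    """

    n_nodes: int = 50
    seed: int = 0
    edge_length_mean_log: float = 0.5  # exp(0.5) ~ 1.6 km
    edge_length_sd_log: float = 0.4
    local_area_shape: float = 4.0
    local_area_scale: float = 0.5
    leaf_attach_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not (0.0 <= self.leaf_attach_prob <= 1.0):
            raise ValueError("leaf_attach_prob must be in [0, 1]")
        if min(self.edge_length_sd_log, self.local_area_shape,
               self.local_area_scale) <= 0:
            raise ValueError("distribution parameters must be positive")


@dataclass(frozen=True)
class SyntheticGenotypeConfig:
    """Island-model genotype settings.

    ``n_per_pop`` may be an int or an inclusive (lo, hi) range from which
    per-population sizes are drawn; the default 15-40 range mirrors typical
    per-site microsatellite sample sizes above the 15-individual inclusion
    filter.  Nine loci is the marker panel size the generator emulates.
    """

    n_pops: int = 10
    n_per_pop: object = (15, 40)
    n_loci: int = 9
    n_alleles: int = 8
    target_fst: float = 0.1
    seed: int = 0
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must be in [0, 1)")
        if min(self.n_pops, self.n_loci, self.n_alleles) <= 0:
            raise ValueError("counts must be positive")


def random_dendritic_network(cfg: SyntheticNetworkConfig) -> RiverNetwork:
    """Grow a random recursive in-tree satisfying all network invariants."""
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_nodes)))
    name = lambda i: f"n{i:0{width}d}"
    g = nx.DiGraph()
    g.add_node(name(0), local_area=float(
        rng.gamma(cfg.local_area_shape, cfg.local_area_scale)
    ))
    leaves = [name(0)]
    for i in range(1, cfg.n_nodes):
        if leaves and rng.random() < cfg.leaf_attach_prob:
            parent = leaves[rng.integers(len(leaves))]
        else:
            nodes = list(g.nodes)
            parent = nodes[rng.integers(len(nodes))]
        new = name(i)
        g.add_node(new, local_area=float(
            rng.gamma(cfg.local_area_shape, cfg.local_area_scale)
        ))
        g.add_edge(new, parent, length=float(
            rng.lognormal(cfg.edge_length_mean_log, cfg.edge_length_sd_log)
        ))
        if parent in leaves and g.in_degree(parent) > 0:
            leaves.remove(parent)
        leaves.append(new)
    return RiverNetwork(g)


def _pop_sizes(cfg: SyntheticGenotypeConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.n_per_pop, int):
        return np.full(cfg.n_pops, cfg.n_per_pop)
    lo, hi = cfg.n_per_pop
    return rng.integers(lo, hi + 1, size=cfg.n_pops)


def island_model_genotypes(
    cfg: SyntheticGenotypeConfig, node_ids=None
) -> GenotypeTable:
    """Genotypes with island-model structure at a configured F_ST.

    Per locus, ancestral frequencies are Dirichlet(1, ..., 1); each
    population's frequencies are Balding-Nichols draws
    Dirichlet(p_anc * (1 - F)/F) (F = 0 means every population shares the
    ancestral vector exactly).  ``target_fst`` is calibrated to the
    *pairwise* Nei F_ST the estimators measure: a pair of islands at
    Balding-Nichols divergence F has expected pairwise F_ST of F/(2 - F)
    (the pair is referenced to its own mean frequencies, not the ancestral
    pool), so the generator draws at F = 2*t/(1 + t) for target t.  Alleles
    are written on a microsatellite-like ladder (100, 102, 104, ...).
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.target_fst
    f_draw = 2.0 * t / (1.0 + t)
    sizes = _pop_sizes(cfg, rng)
    if node_ids is None:
        node_ids = [f"pop{j + 1:02d}" for j in range(cfg.n_pops)]
    ladder = 100 + 2 * np.arange(cfg.n_alleles)
    rows = []
    geno: dict[str, np.ndarray] = {}
    for l in range(cfg.n_loci):
        p_anc = rng.dirichlet(np.ones(cfg.n_alleles))
        copies = []
        for j in range(cfg.n_pops):
            if f_draw > 0:
                conc = p_anc * (1.0 - f_draw) / f_draw
                p = rng.dirichlet(np.maximum(conc, 1e-9))
            else:
                p = p_anc
            draws = rng.choice(cfg.n_alleles, size=(sizes[j], 2), p=p)
            copies.append(ladder[draws])
        geno[f"locus{l + 1}"] = np.concatenate(copies, axis=0)
    pop_of = np.repeat(np.arange(cfg.n_pops), sizes)
    df = pd.DataFrame(
        {
            "individual_id": [f"ind{i + 1:04d}" for i in range(pop_of.size)],
            "node_id": [node_ids[j] for j in pop_of],
            "species": cfg.species,
        }
    )
    for l in range(cfg.n_loci):
        df[f"locus{l + 1}_a1"] = geno[f"locus{l + 1}"][:, 0]
        df[f"locus{l + 1}_a2"] = geno[f"locus{l + 1}"][:, 1]
    return GenotypeTable(df)


# ---------------------------------------------------------------------------
# Worked fixture
# ---------------------------------------------------------------------------

def write_worked_fixture(out_dir) -> dict:
    """Write the byte-stable toy inputs used by the worked examples.

    Files: ``nodes.tsv``/``edges.tsv`` — a 7-node balanced binary tree with
    unit edge lengths and unit local areas; ``genotypes.tsv`` — four
    individuals at one node, two loci, designed so that locus2 has allele
    counts {1,1,1,2} over one pair of individuals' gene copies; and
    ``expected.json`` — hand-derived statistics for those inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # 7-node balanced binary tree: leaves L1..L4 -> C1, C2 -> R (outlet)
    nodes = pd.DataFrame(
        {
            "node_id": ["L1", "L2", "L3", "L4", "C1", "C2", "R"],
            "local_area_km2": [1.0] * 7,
        }
    )
    edges = pd.DataFrame(
        {
            "from_node": ["L1", "L2", "L3", "L4", "C1", "C2"],
            "to_node": ["C1", "C1", "C2", "C2", "R", "R"],
            "length_km": [1.0] * 6,
        }
    )
    nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
    edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    # locus2 of ind1+ind2 has gene copies {100,100,100,102}: AR at g=2 is 1.5
    genotypes = pd.DataFrame(
        {
            "individual_id": ["ind1", "ind2", "ind3", "ind4"],
            "node_id": ["L1"] * 4,
            "species": ["A"] * 4,
            "locus1_a1": [120, 120, 122, 120],
            "locus1_a2": [122, 120, 122, 124],
            "locus2_a1": [100, 100, 100, 102],
            "locus2_a2": [100, 102, 100, 102],
        }
    )
    genotypes.to_csv(out / "genotypes.tsv", sep="\t", index=False)
    expected = {
        "network": {
            "outlet": "R",
            "upstream_distance": {"L1": 2.0, "C1": 1.0, "R": 0.0},
            "catchment_area_outlet": 7.0,
            "instream_distance": {"L1-L2": 2.0, "L1-L4": 4.0, "L1-R": 2.0},
            "degree": {"L1": 1, "C1": 3, "R": 2},
        },
        "genotypes": {
            "n_individuals": 4,
            "ar_locus2_first_two_inds_g2": 1.5,
            "ho_locus1": 0.5,
        },
    }
    with open(out / "expected.json", "w") as fh:
        json.dump(expected, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return expected
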