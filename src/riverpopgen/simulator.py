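"""Individual-based, discrete-time metapopulation genetic simulator.

The model tracks diploid, sexually reproducing individuals (sex ratio 0.5)
on the nodes of a :class:`~riverpopgen.network.RiverNetwork`.  Generations
are non-overlapping; each generation runs

    reproduction -> mutation -> natal dispersal -> census.

Reproduction is density-regulated by a Beverton-Holt function: a female in
node i with at least one local male produces a Poisson number of offspring
with mean 2*lambda0 / (1 + (lambda0 - 1) * N_i / K_i), where N_i counts all
adults present at the start of reproduction.  The factor 2 on the female
fecundity compensates for the 0.5 sex ratio so that the population
equilibrates at the carrying capacity K_i.  Fathers are drawn uniformly with
replacement among local males; each offspring inherits one uniformly chosen
allele per locus from each parent.

Genetics: ``n_loci`` neutral, unlinked diploid loci with allele states
1..``n_allele_states`` (default 100).  Each allele copy mutates
independently with probability ``mu`` per generation under either

* ``stepwise``: +/-1 with equal probability, reflecting at both ends of the
  ladder (from the lowest state always +1, from the highest always -1), or
* ``random``: a fresh state uniform over all states (possibly the current
  one, so the effective change rate is mu*(1 - 1/n_states)).

Dispersal is natal and nearest-neighbour: each offspring emigrates with
probability ``d``; the target is drawn among adjacent nodes with weight 1
for the downstream neighbour and weight ``W`` for each upstream neighbour
(W = 0: pure downstream drift, W = 1: direction-blind).  If every weight is
zero (an outlet with W = 0) the individual stays.  Dispersal mortality ``m``
(default 0) removes migrants in transit.

Carrying capacities are either uniform (``k_mode="fixed"``: K_i = K_base)
or scale with the square root of the accumulated catchment area
(``k_mode="scaled"``), normalized so the metapopulation total stays at
n_nodes * K_base and floored at 2 individuals per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
import yaml

from .network import RiverNetwork, catchment_accumulation
from .popgen import GenotypeTable

__all__ = [
    "SimulationParams",
    "MetapopState",
    "ReplicateResult",
    "scaled_capacities",
    "node_capacities",
    "initialize_state",
    "reproduction_step",
    "mutation_step",
    "dispersal_step",
    "run",
    "state_to_genotype_table",
]


@dataclass(frozen=True)
class SimulationParams:
    """Scenario definition for one simulator run.

    Defaults mirror the fixed study conditions: mean carrying capacity 1000,
    mutation rate 1e-4, fecundity lambda0 = 2, no dispersal mortality, ten
    loci with 100 allele states, 10,000 generations, ten replicates.
    """

    d: float = 0.01
    W: float = 0.5
    k_mode: Literal["fixed", "scaled"] = "fixed"
    K_base: int = 1000
    mu: float = 1e-4
    lambda0: float = 2.0
    m: float = 0.0
    n_loci: int = 10
    n_allele_states: int = 100
    mut_model: Literal["stepwise", "random"] = "stepwise"
    generations: int = 10_000
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.d <= 1.0):
            raise ValueError("dispersal rate d must be in [0, 1]")
        if not (0.0 <= self.W <= 1.0):
            raise ValueError("upstream movement probability W must be in [0, 1]")
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mutation rate mu must be in [0, 1]")
        if not self.lambda0 > 1.0:
            raise ValueError("fecundity lambda0 must exceed 1")
        if not (0.0 <= self.m <= 1.0):
            raise ValueError("dispersal mortality m must be in [0, 1]")
        if min(self.K_base, self.n_loci, self.n_allele_states, self.generations,
               self.replicates) <= 0:
            raise ValueError("counts must be positive")
        if self.k_mode not in ("fixed", "scaled"):
            raise ValueError("k_mode must be 'fixed' or 'scaled'")
        if self.mut_model not in ("stepwise", "random"):
            raise ValueError("mut_model must be 'stepwise' or 'random'")

    def scenario_label(self) -> str:
        return (
            f"d={self.d}_W={self.W}_K={self.k_mode}_mut={self.mut_model}"
        )

    @classmethod
    def from_yaml(cls, path) -> "SimulationParams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        return cls(**cfg)


@dataclass
class MetapopState:
    """Flat arrays over all living individuals plus per-node capacities."""

    node: np.ndarray  # (N,) int32 node index
    female: np.ndarray  # (N,) bool
    geno: np.ndarray  # (N, n_loci, 2) int16 allele states
    K: np.ndarray  # (n_nodes,) int capacities
    generation: int = 0

    @property
    def n(self) -> int:
        return self.node.size

    def node_counts(self) -> np.ndarray:
        return np.bincount(self.node, minlength=self.K.size)


@dataclass
class ReplicateResult:
    replicate: int
    genotypes: GenotypeTable | None
    trajectory: pd.DataFrame
    extinct: bool


# ---------------------------------------------------------------------------
# Capacities and initialization
# ---------------------------------------------------------------------------

def scaled_capacities(net: RiverNetwork, K_base: int = 1000) -> dict:
    """Capacities proportional to sqrt(accumulated catchment area),
    normalized so the total equals n_nodes * K_base and floored at 2.

    The outlet accumulates the whole basin, so it receives the maximum K.
    """
    acc = catchment_accumulation(net)
    nodes = net.nodes
    w = np.sqrt(np.array([acc[n] for n in nodes], dtype=float))
    if w.sum() <= 0:
        raise ValueError("total catchment area is zero; cannot scale capacities")
    total = net.n_nodes * K_base
    k = np.maximum(np.round(w / w.sum() * total).astype(int), 2)
    return dict(zip(nodes, k.tolist()))


def node_capacities(net: RiverNetwork, params: SimulationParams) -> np.ndarray:
    nodes = net.nodes
    if params.k_mode == "fixed":
        return np.full(len(nodes), params.K_base, dtype=np.int64)
    sc = scaled_capacities(net, params.K_base)
    return np.array([sc[n] for n in nodes], dtype=np.int64)


def initialize_state(
    net: RiverNetwork, params: SimulationParams, rng: np.random.Generator
) -> MetapopState:
    """Seed every node at its capacity with uniform-random alleles and sexes."""
    K = node_capacities(net, params)
    node = np.repeat(np.arange(K.size, dtype=np.int32), K)
    n = node.size
    female = rng.random(n) < 0.5
    geno = rng.integers(
        1, params.n_allele_states + 1, size=(n, params.n_loci, 2), dtype=np.int16
    )
    return MetapopState(node=node, female=female, geno=geno, K=K)


def _neighbour_tables(net: RiverNetwork, W: float):
    """Per-node adjacent targets and cumulative dispersal weights.

    Weight 1 for the downstream neighbour, W per upstream neighbour.
    Returns (targets, cumw, has_target): targets (n_nodes, maxdeg) int32
    padded with -1, cumw cumulative weights normalized to 1 where the total
    weight is positive, has_target bool per node.
    """
    nodes = net.nodes
    index = {n: i for i, n in enumerate(nodes)}
    nbrs, weights = [], []
    for n in nodes:
        t, w = [], []
        dn = net.downstream_neighbour(n)
        if dn is not None:
            t.append(index[dn])
            w.append(1.0)
        for up in net.upstream_neighbours(n):
            if W > 0:
                t.append(index[up])
                w.append(W)
        nbrs.append(t)
        weights.append(w)
    maxdeg = max(1, max(len(t) for t in nbrs))
    targets = np.full((len(nodes), maxdeg), -1, dtype=np.int32)
    cumw = np.full((len(nodes), maxdeg), np.inf)
    has_target = np.zeros(len(nodes), dtype=bool)
    for i, (t, w) in enumerate(zip(nbrs, weights)):
        tot = sum(w)
        if tot > 0:
            targets[i, : len(t)] = t
            cumw[i, : len(t)] = np.cumsum(np.asarray(w) / tot)
            has_target[i] = True
    return targets, cumw, has_target


# ---------------------------------------------------------------------------
# Life-cycle steps
# ---------------------------------------------------------------------------

def reproduction_step(
    state: MetapopState, params: SimulationParams, rng: np.random.Generator
) -> MetapopState:
    """Beverton-Holt density-regulated sexual reproduction; the offspring
    generation replaces the adults (non-overlapping generations)."""
    n_nodes = state.K.size
    N = state.node_counts()
    males_per_node = np.bincount(state.node[~state.female], minlength=n_nodes)
    mean_off = 2.0 * params.lambda0 / (
        1.0 + (params.lambda0 - 1.0) * N / state.K
    )
    mothers_all = np.where(state.female & (males_per_node[state.node] > 0))[0]
    n_off = rng.poisson(mean_off[state.node[mothers_all]])
    mothers = np.repeat(mothers_all, n_off)
    M = mothers.size
    n_loci = state.geno.shape[1]
    if M == 0:
        empty = MetapopState(
            node=np.empty(0, np.int32),
            female=np.empty(0, bool),
            geno=np.empty((0, n_loci, 2), np.int16),
            K=state.K,
            generation=state.generation,
        )
        return empty
    # uniform local father per offspring, sampled with replacement
    male_idx = np.where(~state.female)[0]
    order = np.argsort(state.node[male_idx], kind="stable")
    males_sorted = male_idx[order]
    offsets = np.concatenate([[0], np.cumsum(males_per_node)])
    mnode = state.node[mothers]
    pick = (rng.random(M) * males_per_node[mnode]).astype(np.int64)
    fathers = males_sorted[offsets[mnode] + pick]
    # Mendelian inheritance: one random allele per locus from each parent
    gm = state.geno[mothers]
    gf = state.geno[fathers]
    cm = rng.integers(0, 2, size=(M, n_loci))
    cf = rng.integers(0, 2, size=(M, n_loci))
    am = np.take_along_axis(gm, cm[:, :, None], axis=2)[:, :, 0]
    af = np.take_along_axis(gf, cf[:, :, None], axis=2)[:, :, 0]
    geno = np.stack([am, af], axis=2).astype(np.int16)
    female = rng.random(M) < 0.5
    return MetapopState(
        node=mnode.astype(np.int32),
        female=female,
        geno=geno,
        K=state.K,
        generation=state.generation,
    )


def mutation_step(
    state: MetapopState, params: SimulationParams, rng: np.random.Generator
) -> MetapopState:
    """Per-allele-copy mutation at rate mu under the configured model."""
    if state.n == 0 or params.mu == 0.0:
        return state
    geno = state.geno
    hit = rng.random(geno.shape) < params.mu
    n_hit = int(hit.sum())
    if n_hit == 0:
        return state
    top = params.n_allele_states
    if params.mut_model == "stepwise":
        step = rng.integers(0, 2, size=n_hit, dtype=np.int16) * 2 - 1
        new = geno[hit] + step
        new[new < 1] = 2  # reflect off the bottom of the ladder
        new[new > top] = top - 1  # reflect off the top
    else:
        new = rng.integers(1, top + 1, size=n_hit, dtype=np.int16)
    geno = geno.copy()
    geno[hit] = new
    return replace(state, geno=geno)


def dispersal_step(
    state: MetapopState,
    params: SimulationParams,
    rng: np.random.Generator,
    neighbour_tables=None,
    net: RiverNetwork | None = None,
) -> MetapopState:
    """Natal nearest-neighbour dispersal with downstream bias 1 : W."""
    if state.n == 0 or params.d == 0.0:
        return state
    if neighbour_tables is None:
        if net is None:
            raise ValueError("pass either neighbour_tables or net")
        neighbour_tables = _neighbour_tables(net, params.W)
    targets, cumw, has_target = neighbour_tables
    node = state.node.copy()
    mig = (rng.random(state.n) < params.d) & has_target[node]
    idx = np.where(mig)[0]
    if idx.size:
        rows = node[idx]
        r = rng.random(idx.size)
        choice = (r[:, None] >= cumw[rows]).sum(axis=1)
        node[idx] = targets[rows, choice]
    keep = np.ones(state.n, dtype=bool)
    if params.m > 0 and idx.size:
        dead = idx[rng.random(idx.size) < params.m]
        keep[dead] = False
    return MetapopState(
        node=node[keep],
        female=state.female[keep],
        geno=state.geno[keep],
        K=state.K,
        generation=state.generation,
    )


# ---------------------------------------------------------------------------
# Summaries and the main loop
# ---------------------------------------------------------------------------

def _mean_he(state: MetapopState) -> float:
    """Mean plain gene diversity 1 - sum p^2 over occupied nodes and loci."""
    if state.n == 0:
        return float("nan")
    vals = []
    order = np.argsort(state.node, kind="stable")
    node_sorted = state.node[order]
    geno_sorted = state.geno[order]
    bounds = np.searchsorted(node_sorted, np.arange(state.K.size + 1))
    for i in range(state.K.size):
        lo, hi = bounds[i], bounds[i + 1]
        if hi - lo < 1:
            continue
        g = geno_sorted[lo:hi]  # (n_i, L, 2)
        for l in range(g.shape[1]):
            copies = g[:, l, :].ravel()
            _, cnt = np.unique(copies, return_counts=True)
            p = cnt / copies.size
            vals.append(1.0 - float(np.sum(p**2)))
    return float(np.mean(vals)) if vals else float("nan")


def state_to_genotype_table(
    state: MetapopState,
    net: RiverNetwork,
    species_label: str,
    replicate: int = 0,
    n_loci: int | None = None,
) -> GenotypeTable:
    """Export the current individuals in the genotype-table schema (node =
    patch id, species = scenario label)."""
    nodes = net.nodes
    L = state.geno.shape[1] if n_loci is None else n_loci
    df = pd.DataFrame(
        {
            "individual_id": [f"r{replicate}_i{i}" for i in range(state.n)],
            "node_id": [nodes[j] for j in state.node],
            "species": species_label,
        }
    )
    for l in range(L):
        df[f"locus{l + 1}_a1"] = state.geno[:, l, 0].astype(int)
        df[f"locus{l + 1}_a2"] = state.geno[:, l, 1].astype(int)
    return GenotypeTable(df)


def run(
    net: RiverNetwork,
    params: SimulationParams,
    record_every: int = 100,
    species_label: str | None = None,
) -> list[ReplicateResult]:
    """Run all replicates of one scenario.

    Each replicate gets an independent RNG stream spawned from the master
    seed (``SeedSequence(seed).spawn``), so results are bit-reproducible for
    identical (params, seed) and replicates are statistically independent.

    Returns one :class:`ReplicateResult` per replicate with the
    final-generation genotype table (``None`` if the metapopulation went
    extinct) and a trajectory of total N and mean expected heterozygosity
    sampled every ``record_every`` generations.
    """
    label = species_label or params.scenario_label()
    children = np.random.SeedSequence(params.seed).spawn(params.replicates)
    tables = _neighbour_tables(net, params.W)
    results = []
    for rep in range(params.replicates):
        rng = np.random.default_rng(children[rep])
        state = initialize_state(net, params, rng)
        traj = [(0, state.n, _mean_he(state))]
        extinct = False
        for t in range(1, params.generations + 1):
            state = reproduction_step(state, params, rng)
            state = mutation_step(state, params, rng)
            state = dispersal_step(state, params, rng, neighbour_tables=tables)
            state.generation = t
            if state.n == 0:
                extinct = True
                traj.append((t, 0, float("nan")))
                break
            if t % record_every == 0 or t == params.generations:
                traj.append((t, state.n, _mean_he(state)))
        gt = (
            None
            if extinct
            else state_to_genotype_table(state, net, label, replicate=rep)
        )
        results.append(
            ReplicateResult(
                replicate=rep,
                genotypes=gt,
                trajectory=pd.DataFrame(
                    traj, columns=["generation", "total_n", "mean_he"]
                ),
                extinct=extinct,
            )
        )
    return results
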