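import networkx as nx
import numpy as np
import pandas as pd
import pytest

from riverpopgen.network import RiverNetwork
from riverpopgen.popgen import GenotypeTable


def make_network(edges, areas=None):
    """Build a RiverNetwork from (upstream, downstream, length) triples."""
    g = nx.DiGraph()
    nodes = {u for e in edges for u in e[:2]}
    areas = areas or {}
    for n in nodes:
        g.add_node(n, local_area=float(areas.get(n, 1.0)))
    for u, v, length in edges:
        g.add_edge(u, v, length=float(length))
    return RiverNetwork(g)


@pytest.fixture
def path_net():
    """3-node path A -> B -> C with lengths 2 and 3; outlet C."""
    return make_network([("A", "B", 2.0), ("B", "C", 3.0)])


@pytest.fixture
def unit_path_net():
    """3-node path with unit lengths."""
    return make_network([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def binary_tree_net():
    """7-node balanced binary tree, unit lengths, unit areas; outlet R."""
    return make_network(
        [
            ("L1", "C1", 1.0),
            ("L2", "C1", 1.0),
            ("L3", "C2", 1.0),
            ("L4", "C2", 1.0),
            ("C1", "R", 1.0),
            ("C2", "R", 1.0),
        ]
    )


def make_genotypes(rows, loci=("locus1", "locus2")):
    """GenotypeTable from rows of (ind, node, species, call-per-locus),
    where a call is a (a1, a2) tuple or None for missing."""
    recs = []
    for ind, node, sp, calls in rows:
        rec = {"individual_id": ind, "node_id": node, "species": sp}
        for loc, call in zip(loci, calls):
            a1, a2 = call if call is not None else (-1, -1)
            rec[f"{loc}_a1"] = a1
            rec[f"{loc}_a2"] = a2
        recs.append(rec)
    return GenotypeTable(pd.DataFrame(recs))


@pytest.fixture
def toy_genotypes():
    """Four individuals at one node, two loci, no missing data."""
    return make_genotypes(
        [
            ("i1", "L1", "A", [(120, 122), (100, 100)]),
            ("i2", "L1", "A", [(120, 120), (100, 102)]),
            ("i3", "L1", "A", [(122, 122), (100, 100)]),
            ("i4", "L1", "A", [(120, 124), (102, 102)]),
        ]
    )


# ---------------------------------------------------------------------------
# Independent graph oracles (pure Python, no networkx)
# ---------------------------------------------------------------------------

def tree_paths(edge_list):
    """All-pairs unique paths on an (undirected) tree given directed edges.

    Returns dict[(a, b)] -> (distance, [nodes on path incl. endpoints]),
    found by depth-first search on the undirected adjacency.
    """
    adj = {}
    for u, v, w in edge_list:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))
    out = {}
    for start in adj:
        stack = [(start, [start], 0.0)]
        seen = {start}
        while stack:
            node, path, dist = stack.pop()
            out[(start, node)] = (dist, path)
            for nbr, w in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    stack.append((nbr, path + [nbr], dist + w))
    return out


def brute_betweenness_undirected(edge_list):
    """Raw betweenness on a tree: count unordered pairs whose unique path
    passes through each node (endpoints excluded)."""
    paths = tree_paths(edge_list)
    nodes = sorted({u for e in edge_list for u in e[:2]})
    counts = {n: 0.0 for n in nodes}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            for mid in paths[(a, b)][1][1:-1]:
                counts[mid] += 1.0
    return counts


def brute_betweenness_directed(edge_list):
    """Raw betweenness counting ordered pairs reachable along downstream
    edges (a path exists iff the undirected tree path follows flow)."""
    down = {u: (v, w) for u, v, w in edge_list}
    nodes = sorted({u for e in edge_list for u in e[:2]})
    counts = {n: 0.0 for n in nodes}
    for a in nodes:
        path = [a]
        node = a
        while node in down:
            node = down[node][0]
            path.append(node)
            for mid in path[1:-1]:
                counts[mid] += 1.0
    return counts
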