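"""River-network data model and graph-theoretic node metrics.

A river network is represented as an in-tree: every node is a subcatchment,
every edge points from a node to its unique downstream neighbour and carries
the instream length (km) between the two subcatchment outlets.  Exactly one
node — the outlet of the whole basin — has no downstream edge.  Node metrics
(upstream distance, accumulated catchment area, betweenness, closeness,
degree) are the connectivity predictors used by the regression layer.

Conventions
-----------
* Edges are stored upstream -> downstream; "directed" metrics follow this
  flow orientation, so directed reachability means "can drift downstream to".
* All shortest-path computations are weighted by edge length.
* Directed closeness excludes unreachable ordered pairs from the distance
  sum (on an in-tree most ordered pairs are mutually unreachable, so an
  infinite-distance convention would zero every value).
* Betweenness is reported as raw (unnormalized) path counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RiverNetwork",
    "NetworkValidationError",
    "CycleError",
    "MultipleOutletsError",
    "MultipleDownstreamError",
    "NonPositiveLengthError",
    "DegenerateSpreadError",
    "read_network",
    "write_network",
    "upstream_distances",
    "catchment_accumulation",
    "betweenness",
    "closeness",
    "standardize_closeness",
    "degree",
    "instream_distance_matrix",
    "node_metrics_table",
]


class NetworkValidationError(ValueError):
    """Base class for river-network topology violations."""


class CycleError(NetworkValidationError):
    pass


class MultipleOutletsError(NetworkValidationError):
    pass


class MultipleDownstreamError(NetworkValidationError):
    pass


class NonPositiveLengthError(NetworkValidationError):
    pass


class DegenerateSpreadError(ValueError):
    """All closeness values equal; min-max standardization undefined."""


@dataclass(frozen=True)
class RiverNetwork:
    """Directed in-tree of subcatchment nodes.

    Parameters
    ----------
    graph
        ``networkx.DiGraph`` with edges oriented upstream -> downstream.
        Node attribute ``local_area`` (km^2, >= 0) is required; optional
        ``x``/``y`` coordinates are carried through I/O.  Edge attribute
        ``length`` (km, > 0) is required.
    """

    graph: nx.DiGraph = field(repr=False)

    def __post_init__(self) -> None:
        validate_topology(self.graph)

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def outlet(self) -> Hashable:
        return next(n for n in self.graph.nodes if self.graph.out_degree(n) == 0)

    def local_area(self, node: Hashable) -> float:
        return float(self.graph.nodes[node]["local_area"])

    def downstream_neighbour(self, node: Hashable):
        """The unique downstream neighbour, or ``None`` at the outlet."""
        succ = list(self.graph.successors(node))
        return succ[0] if succ else None

    def upstream_neighbours(self, node: Hashable) -> list:
        return list(self.graph.predecessors(node))

    def undirected(self) -> nx.Graph:
        return self.graph.to_undirected(as_view=False)

    @classmethod
    def from_tables(cls, nodes: pd.DataFrame, edges: pd.DataFrame) -> "RiverNetwork":
        """Build from a node table (node_id, local_area_km2[, x, y]) and an
        edge table (from_node, to_node, length_km)."""
        g = nx.DiGraph()
        for row in nodes.itertuples(index=False):
            attrs = {"local_area": float(row.local_area_km2)}
            for c in ("x", "y"):
                if hasattr(row, c) and pd.notna(getattr(row, c)):
                    attrs[c] = float(getattr(row, c))
            g.add_node(row.node_id, **attrs)
        known = set(g.nodes)
        for row in edges.itertuples(index=False):
            for end in (row.from_node, row.to_node):
                if end not in known:
                    raise NetworkValidationError(
                        f"edge {row.from_node}->{row.to_node} references undeclared node {end!r}"
                    )
            g.add_edge(row.from_node, row.to_node, length=float(row.length_km))
        return cls(g)


def validate_topology(g: nx.DiGraph) -> None:
    """Check the in-tree invariants, raising a named error per violation."""
    if g.number_of_nodes() == 0:
        raise NetworkValidationError("network has no nodes")
    for u, v, data in g.edges(data=True):
        length = data.get("length")
        if length is None or not length > 0:
            raise NonPositiveLengthError(
                f"edge {u}->{v} has non-positive or missing length {length!r}"
            )
    for n, data in g.nodes(data=True):
        if data.get("local_area", 0.0) < 0:
            raise NetworkValidationError(f"node {n} has negative local area")
    multi = [n for n in g.nodes if g.out_degree(n) > 1]
    if multi:
        raise MultipleDownstreamError(
            f"node(s) with more than one downstream edge: {multi[:5]}"
        )
    outlets = [n for n in g.nodes if g.out_degree(n) == 0]
    if len(outlets) > 1:
        raise MultipleOutletsError(f"multiple outlet nodes: {outlets[:5]}")
    if len(outlets) == 0:
        # every node has a downstream edge => there must be a cycle
        cyc = nx.find_cycle(g)
        raise CycleError(f"cycle detected: {cyc}")
    try:
        cyc = nx.find_cycle(g)
        raise CycleError(f"cycle detected: {cyc}")
    except nx.NetworkXNoCycle:
        pass
    if not nx.is_weakly_connected(g):
        raise NetworkValidationError("network is not connected")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_network(node_table_path, edge_table_path) -> RiverNetwork:
    """Read a river network from a node TSV and an edge TSV.

    Node table columns: ``node_id``, ``local_area_km2`` and optionally
    ``x``/``y``.  Edge table columns: ``from_node`` (upstream), ``to_node``
    (downstream), ``length_km``.
    """
    nodes = pd.read_csv(node_table_path, sep="\t", dtype={"node_id": str})
    edges = pd.read_csv(
        edge_table_path, sep="\t", dtype={"from_node": str, "to_node": str}
    )
    return RiverNetwork.from_tables(nodes, edges)


def write_network(net: RiverNetwork, node_table_path, edge_table_path) -> None:
    rows = []
    for n, data in net.graph.nodes(data=True):
        row = {"node_id": n, "local_area_km2": data["local_area"]}
        for c in ("x", "y"):
            if c in data:
                row[c] = data[c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(node_table_path, sep="\t", index=False)
    pd.DataFrame(
        [
            {"from_node": u, "to_node": v, "length_km": d["length"]}
            for u, v, d in net.graph.edges(data=True)
        ]
    ).to_csv(edge_table_path, sep="\t", index=False)


def read_graphml(path) -> RiverNetwork:
    g = nx.read_graphml(path)
    h = nx.DiGraph()
    for n, data in g.nodes(data=True):
        h.add_node(n, **{k: data[k] for k in ("local_area", "x", "y") if k in data})
    for u, v, data in g.edges(data=True):
        h.add_edge(u, v, length=float(data["length"]))
    return RiverNetwork(h)


def write_graphml(net: RiverNetwork, path) -> None:
    nx.write_graphml(net.graph, path)


# ---------------------------------------------------------------------------
# Node metrics
# ---------------------------------------------------------------------------

def upstream_distances(net: RiverNetwork) -> dict:
    """Instream distance (km) from each node to the basin outlet.

    The downstream path is unique on an in-tree, so the distance is the sum
    of edge lengths along it; the outlet itself is at distance 0.
    """
    rev = net.graph.reverse(copy=False)
    dist: dict = {net.outlet: 0.0}
    stack = [net.outlet]
    while stack:
        v = stack.pop()
        for u in rev.successors(v):
            dist[u] = dist[v] + net.graph.edges[u, v]["length"]
            stack.append(u)
    return dist


def catchment_accumulation(net: RiverNetwork) -> dict:
    """Total upstream catchment area (km^2) per node: the node's own local
    area plus the accumulated areas of its immediate upstream neighbours."""
    total: dict = {}
    for n in nx.topological_sort(net.graph):
        total[n] = net.local_area(n) + sum(
            total[u] for u in net.graph.predecessors(n)
        )
    return total


def betweenness(net: RiverNetwork, directed: bool = False) -> dict:
    """Weighted shortest-path betweenness, raw (unnormalized) counts,
    endpoints excluded.  Directed mode follows the downstream orientation."""
    g = net.graph if directed else net.undirected()
    return nx.betweenness_centrality(g, normalized=False, weight="length")


def closeness(net: RiverNetwork, directed: bool = False) -> dict:
    """Closeness as the reciprocal of the summed instream distances from a
    node to every other node.

    In directed mode distances follow downstream edges and unreachable
    ordered pairs are excluded from the sum; a node that reaches no other
    node gets closeness 0.
    """
    result = {}
    g = net.graph if directed else net.undirected()
    for n in g.nodes:
        lengths = nx.single_source_dijkstra_path_length(g, n, weight="length")
        s = sum(v for k, v in lengths.items() if k != n)
        result[n] = 1.0 / s if s > 0 else 0.0
    return result


def standardize_closeness(values: Mapping) -> dict:
    """Min-max standardization to [0, 1]: (c_i - min c) / (max c - min c)."""
    arr = np.asarray(list(values.values()), dtype=float)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise DegenerateSpreadError(
            "all closeness values are equal; standardization undefined"
        )
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def degree(net: RiverNetwork) -> dict:
    """Undirected degree (number of incident channels)."""
    return dict(net.undirected().degree())


def instream_distance_matrix(
    net: RiverNetwork, subset: Sequence | None = None
) -> pd.DataFrame:
    """Symmetric matrix of along-network (tree-path) distances in km.

    Parameters
    ----------
    subset
        Node ids to include (default: all nodes, in graph order).
    """
    nodes = list(net.nodes) if subset is None else list(subset)
    unknown = [n for n in nodes if n not in net.graph]
    if unknown:
        raise KeyError(f"unknown node id(s): {unknown[:5]}")
    # tree-path distance via distances to the outlet and lowest common
    # ancestor in the downstream direction:
    # d(i,j) = up(i) + up(j) - 2 up(lca(i,j))
    up = upstream_distances(net)
    down = {n: net.downstream_neighbour(n) for n in net.graph.nodes}
    # downstream path node sets, memoized per queried node
    def path_to_outlet(n):
        out = []
        while n is not None:
            out.append(n)
            n = down[n]
        return out

    paths = {n: path_to_outlet(n) for n in nodes}
    k = len(nodes)
    mat = np.zeros((k, k))
    for i in range(k):
        pi = set(paths[nodes[i]])
        for j in range(i + 1, k):
            # deepest common node on both downstream paths
            lca = next(n for n in paths[nodes[j]] if n in pi)
            d = up[nodes[i]] + up[nodes[j]] - 2.0 * up[lca]
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=nodes, columns=nodes)


def node_metrics_table(net: RiverNetwork) -> pd.DataFrame:
    """All per-node metrics as a tidy table (one row per node).

    Columns: upstream_distance, catchment_area, betweenness_directed,
    betweenness_undirected, closeness_directed, closeness_undirected,
    closeness_std (min-max standardized undirected closeness), degree.
    """
    up = upstream_distances(net)
    acc = catchment_accumulation(net)
    bd = betweenness(net, directed=True)
    bu = betweenness(net, directed=False)
    cd = closeness(net, directed=True)
    cu = closeness(net, directed=False)
    cs = standardize_closeness(cu) if len(set(cu.values())) > 1 else {k: 0.0 for k in cu}
    deg = degree(net)
    nodes = net.nodes
    return pd.DataFrame(
        {
            "node_id": nodes,
            "upstream_distance": [up[n] for n in nodes],
            "catchment_area": [acc[n] for n in nodes],
            "betweenness_directed": [bd[n] for n in nodes],
            "betweenness_undirected": [bu[n] for n in nodes],
            "closeness_directed": [cd[n] for n in nodes],
            "closeness_undirected": [cu[n] for n in nodes],
            "closeness_std": [cs[n] for n in nodes],
            "degree": [deg[n] for n in nodes],
        }
    ).set_index("node_id")
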