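"""Scoring primitives for robustness-based complex detection.

All functions operate on a simple undirected ``networkx.Graph`` whose nodes
are protein identifiers.  They implement, in order: the Jaccard edge weight
w_uv, the pruned neighbourhood graph G_v' and the node weight w_v derived
from it, the modified Czekanovski-Dice distance d(v, K) between a cluster
and a frontier node, the robustness degree R_K obtained by iterated
max-degree node removal, and the neighbour affinity NA(A, B) used both for
cluster merging and for matching predictions against reference complexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx


@dataclass(frozen=True)
class NeighbourhoodGraph:
    """Degree-1-pruned neighbourhood graph G_v' of a centre node.

    ``retained_nodes`` is V'': the centre plus those neighbours that keep
    degree >= 2 inside the induced neighbourhood graph G_v.  Pruning is a
    single simultaneous pass over G_v degrees (not an iterated core peel).
    """

    centre: str
    retained_nodes: frozenset[str]
    retained_edges: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class DistanceBreakdown:
    """Intermediate counts behind the cluster-node distance d(v, K)."""

    size_K: int
    m: int
    deg_K: int
    deg_v: int
    out_K: int
    out_v: int
    d: float


@dataclass(frozen=True)
class RobustnessResult:
    """Outcome of iterated max-degree removal on a connected subgraph."""

    n_removed: int
    initial_size: int
    R: float


def edge_weight(net: nx.Graph, u: str, v: str) -> float:
    """Jaccard similarity of the endpoint neighbourhoods of an edge.

    w_uv = |Γ(u) ∩ Γ(v)| / |Γ(u) ∪ Γ(v)|.  Defined only on edges; since u
    and v are then each other's neighbours the union is never empty.
    """
    if not net.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is not an edge; edge weights are defined on edges only")
    gu, gv = set(net[u]), set(net[v])
    return len(gu & gv) / len(gu | gv)


def neighbourhood_graph(net: nx.Graph, v: str) -> NeighbourhoodGraph:
    """Build G_v (centre, neighbours, induced edges) and prune degree-1 nodes.

    All nodes whose degree within G_v is exactly 1 are removed in one
    simultaneous pass, together with their incident edges — including the
    centre itself when it has a single neighbour.
    """
    if v not in net:
        raise ValueError(f"unknown node: {v!r}")
    gv_nodes = {v} | set(net[v])
    sub = net.subgraph(gv_nodes)
    retained = frozenset(u for u in gv_nodes if sub.degree(u) != 1)
    edges = frozenset(
        tuple(sorted((a, b))) for a, b in sub.edges() if a in retained and b in retained
    )
    return NeighbourhoodGraph(centre=v, retained_nodes=retained, retained_edges=edges)


def node_weight(net: nx.Graph, v: str) -> float:
    """Average degree of the pruned neighbourhood graph G_v' (0 when empty).

    Equals 2·|E'| / |V''|; a high value marks a node whose neighbourhood is
    densely interconnected, i.e. a good expansion seed.
    """
    ng = neighbourhood_graph(net, v)
    if not ng.retained_nodes:
        return 0.0
    return 2.0 * len(ng.retained_edges) / len(ng.retained_nodes)


def cluster_node_distance(net: nx.Graph, K: Iterable[str], v: str) -> DistanceBreakdown:
    """Modified Czekanovski-Dice distance between cluster K and node v.

        d(v,K) = (|K| - m)/|K| + (OUT(K) + OUT(v)) / (deg(K) + deg(v) - 2m + |K|)

    where m counts edges between v and K, deg(K) is the external degree of K
    (edges with exactly one endpoint in K, edges to v included), deg(v) the
    degree of v, and OUT(·) excludes edges towards v, K and the common
    neighbours CN = {u ∉ K, u ≠ v : u ~ v and u ~ K}.  Lower distance means
    v is more strongly tied to K, directly or through shared neighbours.
    """
    members = set(K)
    if not members:
        raise ValueError("K must be non-empty")
    if v in members:
        raise ValueError(f"{v!r} is already a member of K")
    gv = set(net[v])
    deg_v = len(gv)
    m = len(gv & members)
    # common neighbours of K and v: adjacent to v and to at least one member
    cn = {u for u in gv - members if u != v and not members.isdisjoint(net[u])}
    deg_K = 0
    out_K = 0
    for k in members:
        for nb in net[k]:
            if nb not in members:
                deg_K += 1
                if nb != v and nb not in cn:
                    out_K += 1
    out_v = sum(1 for nb in gv if nb not in members and nb not in cn)
    denom = deg_K + deg_v - 2 * m + len(members)
    d = (len(members) - m) / len(members) + (out_K + out_v) / denom
    return DistanceBreakdown(
        size_K=len(members), m=m, deg_K=deg_K, deg_v=deg_v, out_K=out_K, out_v=out_v, d=d
    )


def robustness(members: Iterable[str], edges: Iterable[tuple[str, str]]) -> RobustnessResult:
    """Robustness degree of a connected cluster by iterated max-degree removal.

    Repeatedly delete the node of highest current degree (ties broken by
    lexicographically smallest ID) with its incident edges, until the
    remainder is disconnected or empty.  R = removals / original size; a
    single node scores 1.0, a star scores 1/(k+1), a clique scores 1.0.
    """
    g = nx.Graph()
    g.add_nodes_from(members)
    g.add_edges_from(edges)
    initial = g.number_of_nodes()
    if initial == 0:
        raise ValueError("cluster must be non-empty")
    if not nx.is_connected(g):
        raise ValueError("robustness is defined for connected clusters only")
    n_removed = 0
    while g.number_of_nodes() > 0:
        target = min(g.nodes, key=lambda u: (-g.degree(u), u))
        g.remove_node(target)
        n_removed += 1
        if g.number_of_nodes() > 0 and not nx.is_connected(g):
            break
    return RobustnessResult(n_removed=n_removed, initial_size=initial, R=n_removed / initial)


def neighbour_affinity(A: Iterable[str], B: Iterable[str]) -> float:
    """Overlap measure NA(A,B) = |A ∩ B|² / (|A|·|B|), in [0, 1].

    Equals 1 iff A = B; 0 iff disjoint.  Used with threshold 0.5 for merging
    detected clusters and 0.2 (ω) for matching predictions to references.
    """
    sa, sb = set(A), set(B)
    if not sa or not sb:
        raise ValueError("neighbour affinity requires non-empty sets")
    inter = len(sa & sb)
    return inter * inter / (len(sa) * len(sb))
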