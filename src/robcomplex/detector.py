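"""Seeded greedy detection of overlapping protein complexes.

The pipeline has five stages: (1) initialization — weight every edge of the
input graph by the Jaccard coefficient and delete zero-weight edges, which
are typically unreliable interactions; (2) seed selection — the unvisited
node with the highest node weight (average degree of its pruned
neighbourhood graph); (3) cluster formation — grow the cluster one frontier
node at a time in order of increasing cluster-node distance, accepting a
candidate only if the enlarged cluster keeps robustness >= theta and
minimum internal edge weight >= gamma; (4) post-processing — a finished
cluster is merged into the most-overlapping existing cluster when their
neighbour affinity reaches the merge threshold, otherwise appended;
(5) termination — when every node is visited or only weight-0 nodes remain.
Visited status gates seeding only, so members of earlier clusters can be
absorbed again and clusters may overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from robcomplex.network_io import ComplexSet, canonical_complexes
from robcomplex.scores import (
    cluster_node_distance,
    edge_weight,
    neighbour_affinity,
    node_weight,
    robustness,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds steering cluster growth and output.

    theta: minimum robustness degree of every accepted cluster state.
    gamma: minimum Jaccard edge weight inside a cluster.
    min_size: smallest cluster reported (generation still happens below it).
    merge_threshold: neighbour-affinity cutoff for merging a new cluster
    into an existing one.
    """

    theta: float = 0.5
    gamma: float = 0.1
    min_size: int = 3
    merge_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {self.theta}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.min_size < 1:
            raise ValueError(f"min_size must be >= 1, got {self.min_size}")
        if not 0.0 < self.merge_threshold <= 1.0:
            raise ValueError(f"merge_threshold must be in (0, 1], got {self.merge_threshold}")


@dataclass
class Cluster:
    """A detected cluster: its members, originating seed and merge audit flag."""

    members: frozenset[str]
    seed: Optional[str] = None
    merged: bool = False

    def __len__(self) -> int:
        return len(self.members)


def initialize(net: nx.Graph) -> nx.Graph:
    """Weight all edges of the input graph and drop the zero-weight ones.

    Jaccard weights are computed once on the raw graph; the deletions do not
    trigger recomputation.  Nodes losing all edges stay as isolated nodes
    (they will carry node weight 0 and never seed a cluster).
    """
    wnet = nx.Graph()
    wnet.add_nodes_from(net.nodes)
    for u, v in net.edges():
        w = edge_weight(net, u, v)
        if w > 0.0:
            wnet.add_edge(u, v, weight=w)
    return wnet


def node_weight_table(wnet: nx.Graph) -> dict[str, float]:
    """Node weight of every node of the filtered network (seed ranking table)."""
    return {v: node_weight(wnet, v) for v in wnet.nodes}


def select_seed(
    wnet: nx.Graph,
    visited: dict[str, bool],
    weights: Optional[dict[str, float]] = None,
) -> Optional[str]:
    """Highest-node-weight unvisited node, or None to signal termination.

    Returns None when every node is visited, or when the best unvisited
    weight is 0 (all remaining nodes are effectively isolated).  Ties break
    to the lexicographically smallest ID.
    """
    if weights is None:
        weights = node_weight_table(wnet)
    candidates = [v for v in wnet.nodes if not visited.get(v, False)]
    if not candidates:
        return None
    best = min(candidates, key=lambda v: (-weights[v], v))
    if weights[best] <= 0.0:
        return None
    return best


def _induced_quality(wnet: nx.Graph, members: set[str]) -> tuple[float, float]:
    """(robustness, min edge weight) of the induced subgraph on `members`."""
    sub = wnet.subgraph(members)
    rob = robustness(members, sub.edges()).R
    min_w = min((data["weight"] for _, _, data in sub.edges(data=True)), default=1.0)
    return rob, min_w


def expand_cluster(wnet: nx.Graph, seed: str, params: DetectionParams) -> Cluster:
    """Grow a cluster from a seed by greedy frontier absorption.

    At each step the frontier node minimizing the cluster-node distance
    (ties to the smallest ID) is tested: the candidate joins only if the
    enlarged induced subgraph keeps robustness >= theta and minimum edge
    weight >= gamma; otherwise it is blacklisted for the remainder of this
    cluster's growth.  Stops when the frontier is exhausted.
    """
    if seed not in wnet:
        raise ValueError(f"unknown seed: {seed!r}")
    members: set[str] = {seed}
    rejected: set[str] = set()
    while True:
        frontier: set[str] = set()
        for u in members:
            frontier.update(wnet[u])
        frontier -= members
        frontier -= rejected
        if not frontier:
            break
        v = min(frontier, key=lambda x: (cluster_node_distance(wnet, members, x).d, x))
        rob, min_w = _induced_quality(wnet, members | {v})
        if rob >= params.theta and min_w >= params.gamma:
            members.add(v)
        else:
            rejected.add(v)
    return Cluster(members=frozenset(members), seed=seed)


def merge_or_add(existing: list[Cluster], K: Cluster, merge_threshold: float = 0.5) -> list[Cluster]:
    """Merge K into its most-overlapping existing cluster, or append it.

    The existing cluster maximizing NA(K, ·) (ties to the earliest inserted)
    absorbs K's members when the affinity reaches the threshold; the merge
    is single-shot — the union is not cascaded against other clusters nor
    re-checked against theta/gamma.  Mutates and returns `existing`.
    """
    if not K.members:
        raise ValueError("cannot add an empty cluster")
    best_idx, best_na = -1, -1.0
    for idx, other in enumerate(existing):
        na = neighbour_affinity(K.members, other.members)
        if na > best_na:
            best_idx, best_na = idx, na
    if best_idx >= 0 and best_na >= merge_threshold:
        old = existing[best_idx]
        existing[best_idx] = Cluster(members=old.members | K.members, seed=None, merged=True)
    else:
        existing.append(K)
    return existing


def detect_clusters(net: nx.Graph, params: DetectionParams = DetectionParams()) -> list[Cluster]:
    """Run the full pipeline, returning audit-carrying clusters of any size.

    Sub-min_size clusters are generated (their members become visited) but
    filtering to min_size is left to :func:`detect_complexes`.
    """
    wnet = initialize(net)
    weights = node_weight_table(wnet)
    visited = {v: False for v in wnet.nodes}
    clusters: list[Cluster] = []
    while True:
        seed = select_seed(wnet, visited, weights)
        if seed is None:
            break
        visited[seed] = True
        K = expand_cluster(wnet, seed, params)
        rob, min_w = _induced_quality(wnet, set(K.members))
        for u in K.members:
            visited[u] = True
        before = len(clusters)
        merge_or_add(clusters, K, params.merge_threshold)
        logger.info(
            "cluster seed=%s size=%d robustness=%.3f min_weight=%.3f %s",
            seed,
            len(K.members),
            rob,
            min_w,
            "merged" if len(clusters) == before else "appended",
        )
    return clusters


def detect_complexes(net: nx.Graph, params: DetectionParams = DetectionParams()) -> ComplexSet:
    """Detect complexes and return those with >= min_size members, canonically ordered."""
    clusters = detect_clusters(net, params)
    return canonical_complexes(c.members for c in clusters if len(c.members) >= params.min_size)
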