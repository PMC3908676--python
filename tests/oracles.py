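"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use plain double loops over all nodes/edges and
materialize every intermediate set, rather than the optimized neighbour-set
arithmetic of the package.
"""

from __future__ import annotations

import networkx as nx


def naive_cluster_node_distance(net: nx.Graph, K, v):
    """Direct transcription of the modified Czekanovski-Dice distance.

    Returns (m, deg_K, deg_v, out_K, out_v, d) computed by exhaustive
    enumeration: common neighbours CN first, then every count by scanning
    all node pairs.
    """
    K = set(K)
    cn = set()
    for u in net.nodes:
        if u in K or u == v:
            continue
        if net.has_edge(u, v) and any(net.has_edge(u, k) for k in K):
            cn.add(u)
    m = sum(1 for k in K if net.has_edge(v, k))
    deg_K = 0
    out_K = 0
    for k in K:
        for nb in net.neighbors(k):
            if nb not in K:
                deg_K += 1
                if nb != v and nb not in cn:
                    out_K += 1
    deg_v = net.degree(v)
    out_v = 0
    for nb in net.neighbors(v):
        if nb not in K and nb not in cn:
            out_v += 1
    d = (len(K) - m) / len(K) + (out_K + out_v) / (deg_K + deg_v - 2 * m + len(K))
    return m, deg_K, deg_v, out_K, out_v, d


def naive_match_counts(P, B, omega):
    """Double-loop N_cp / N_cb counting with set arithmetic inline."""
    def na(a, b):
        inter = len(set(a) & set(b))
        return inter * inter / (len(set(a)) * len(set(b)))

    n_cp = 0
    for p in P:
        if any(na(p, b) >= omega for b in B):
            n_cp += 1
    n_cb = 0
    for b in B:
        if any(na(p, b) >= omega for p in P):
            n_cb += 1
    return n_cp, n_cb
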