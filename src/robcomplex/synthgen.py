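"""Planted-complex synthetic PPI networks with ground truth.

The generator emulates the structural signal complex detectors exploit:
locally dense groups of proteins (the planted complexes) sitting in a sparse
background of noise interactions.  Each complex is an (almost-)clique drawn
with intra-complex edge probability ``p_within`` and rejection-resampled
until internally connected; consecutive complexes may share exactly one
protein, producing genuinely overlapping ground truth; every remaining node
pair — background-background, background-complex and cross-complex — is
joined with probability ``p_background``.  Everything is reproducible from
``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from robcomplex.network_io import ComplexSet

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a planted-complex network.

    Defaults describe five size-5 planted complexes with 10% of internal
    edges dropped and 1% background noise — a small, noisy regime in which
    a detector should still recover essentially all complexes.
    """

    n_complexes: int = 5
    size_min: int = 5
    size_max: int = 5
    p_within: float = 0.9
    overlap_fraction: float = 0.0
    n_background: int = 0
    p_background: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 0:
            raise ValueError("n_complexes must be >= 0")
        if self.size_min < 3:
            raise ValueError(f"size_min must be >= 3, got {self.size_min}")
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")
        for name in ("p_within", "p_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError(f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


def _sample_internal_edges(
    nodes: list[str], p_within: float, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """Bernoulli-sample internal edges, rejecting until the complex is connected."""
    pairs = list(combinations(nodes, 2))
    for _ in range(_MAX_RESAMPLE):
        edges = [pair for pair in pairs if rng.random() < p_within]
        g = nx.Graph(edges)
        g.add_nodes_from(nodes)
        if nx.is_connected(g):
            return edges
    raise RuntimeError(
        f"could not sample a connected complex of size {len(nodes)} "
        f"with p_within={p_within} in {_MAX_RESAMPLE} attempts"
    )


def generate(cfg: SyntheticConfig) -> tuple[nx.Graph, ComplexSet]:
    """Generate a planted-complex network and its ground-truth complex set.

    Returns the network (isolated background nodes included) and the
    planted complexes in generation order.  With ``p_within=1``,
    ``p_background=0`` and no overlap the network is a disjoint union of
    cliques whose connected components are exactly the ground truth.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    net = nx.Graph()
    truth: list[frozenset[str]] = []
    membership: dict[str, set[int]] = {}
    counter = 0

    def fresh() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:04d}"

    prev: list[str] = []
    for idx in range(cfg.n_complexes):
        size = int(rng.integers(cfg.size_min, cfg.size_max + 1))
        nodes: list[str] = []
        if prev and rng.random() < cfg.overlap_fraction:
            nodes.append(prev[int(rng.integers(len(prev)))])
        while len(nodes) < size:
            nodes.append(fresh())
        edges = _sample_internal_edges(nodes, cfg.p_within, rng)
        net.add_nodes_from(nodes)
        net.add_edges_from(edges)
        truth.append(frozenset(nodes))
        for u in nodes:
            membership.setdefault(u, set()).add(idx)
        prev = nodes

    background = [fresh() for _ in range(cfg.n_background)]
    net.add_nodes_from(background)

    if cfg.p_background > 0.0:
        all_nodes = sorted(net.nodes)
        for u, v in combinations(all_nodes, 2):
            shared = membership.get(u, set()) & membership.get(v, set())
            if shared:
                continue  # internal pairs were sampled with p_within
            if rng.random() < cfg.p_background:
                net.add_edge(u, v)

    return net, truth
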