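"""Dense-module detection by a re-implementation of the MCODE algorithm.

MCODE (molecular complex detection) proceeds in three steps:

1. *Vertex weighting.* For each vertex, take its closed neighborhood (the
   vertex plus its neighbors), extract the highest k-core of that
   neighborhood, and set ``weight(v) = k_max * density(core)`` where density
   is ``2E / (N(N-1))``. Dense, cliquish neighborhoods give high weights.
2. *Complex prediction.* Starting from the highest-weight unvisited vertex,
   greedily grow a complex by recursively including neighbors whose weight
   exceeds ``seed_weight * (1 - vwp)`` (vertex weight percentage, default
   0.2). Each vertex belongs to at most one complex.
3. *Post-processing.* Complexes without a 2-core are discarded (``min_core``)
   and, with *haircut* on, vertices singly connected inside the complex are
   trimmed.

Tie-breaking is everywhere by (weight descending, gene id ascending), which
makes the output deterministic and independent of edge input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "GeneModule",
    "k_core_decomposition",
    "mcode_vertex_weights",
    "mcode_complexes",
    "module_statistics",
    "filter_modules",
]


@dataclass
class GeneModule:
    """A detected module: its members, the seed it grew from, its MCODE score
    (complex density times size), and topology statistics of the induced
    subgraph."""

    members: frozenset[str]
    seed: str
    score: float
    n_nodes: int = 0
    avg_connectivity: float = 0.0
    clustering_coefficient: float = 0.0
    module_id: str = ""

    def __post_init__(self) -> None:
        self.n_nodes = len(self.members)


def k_core_decomposition(graph: nx.Graph) -> dict[str, int]:
    """Core number of every node (iterative peeling)."""
    if graph.number_of_nodes() == 0:
        return {}
    return nx.core_number(graph)


def _density(n: int, e: int) -> float:
    return 2.0 * e / (n * (n - 1)) if n > 1 else 0.0


def mcode_vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """MCODE vertex weight: core level times density of the highest k-core of
    the closed neighborhood; isolated vertices weigh 0."""
    weights: dict[str, float] = {}
    for v in graph:
        nbrs = set(graph.neighbors(v)) | {v}
        if len(nbrs) < 2:
            weights[v] = 0.0
            continue
        nbhd = graph.subgraph(nbrs)
        cores = nx.core_number(nbhd)
        k_max = max(cores.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        top = nbhd.subgraph([u for u, c in cores.items() if c == k_max])
        weights[v] = k_max * _density(top.number_of_nodes(), top.number_of_edges())
    return weights


def mcode_complexes(
    graph: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    min_core: int = 2,
    max_depth: int = 100,
) -> list[GeneModule]:
    """Predict complexes by greedy seeded expansion over vertex weights.

    Parameters follow the Cytoscape plugin defaults: ``vwp`` 0.2, haircut on,
    fluff off, ``min_core`` 2, depth limit 100. Complexes are returned in
    decreasing score order (score = density of the complex times its size).
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not provided")
    if not 0.0 <= vwp < 1.0:
        raise ValueError("vwp must be in [0, 1)")
    weights = mcode_vertex_weights(graph)
    # seeds in deterministic order: weight descending, id ascending
    order = sorted(graph.nodes(), key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    complexes: list[GeneModule] = []
    for seed in order:
        if seed in visited or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [(seed, 0)]
        claimed = visited | {seed}
        while frontier:
            v, depth = frontier.pop(0)
            if depth >= max_depth:
                continue
            for u in sorted(graph.neighbors(v), key=str):
                if u in claimed:
                    continue
                claimed.add(u)  # examined once per complex, MCODE-style
                if weights[u] > threshold:
                    members.add(u)
                    frontier.append((u, depth + 1))
        sub = graph.subgraph(members)
        # min_core: discard complexes not containing a k-core of min_core
        if members and max(nx.core_number(sub).values(), default=0) < min_core:
            visited |= members
            continue
        if haircut:
            members = {v for v in members if sub.degree(v) >= 2}
            sub = graph.subgraph(members)
        if len(members) < 2 or not nx.is_connected(sub):
            # haircut can disconnect; keep the largest component (ties by
            # smallest gene id) so every module induces a connected subgraph
            comps = sorted(
                nx.connected_components(sub), key=lambda c: (-len(c), min(map(str, c)))
            )
            if not comps or len(comps[0]) < 2:
                visited |= members
                continue
            members = set(comps[0])
            sub = graph.subgraph(members)
        visited |= set(sub.nodes()) | members
        score = _density(sub.number_of_nodes(), sub.number_of_edges()) * len(members)
        complexes.append(
            GeneModule(members=frozenset(members), seed=seed, score=score)
        )
    complexes.sort(key=lambda m: (-m.score, min(m.members)))
    for i, mod in enumerate(complexes, start=1):
        mod.module_id = f"M{i}"
    return complexes


def module_statistics(module: GeneModule, graph: nx.Graph) -> GeneModule:
    """Fill in average connectivity and clustering coefficient computed on the
    module's induced subgraph."""
    sub = graph.subgraph(module.members)
    degs = [d for _, d in sub.degree()]
    module.avg_connectivity = float(np.mean(degs)) if degs else 0.0
    module.clustering_coefficient = (
        float(nx.average_clustering(sub)) if sub.number_of_nodes() > 0 else 0.0
    )
    return module


def filter_modules(
    modules: list[GeneModule],
    graph: nx.Graph,
    min_nodes: int = 10,
    min_avg_connectivity: float = 10.0,
    min_cc: float = 0.5,
) -> list[GeneModule]:
    """Keep modules with at least ``min_nodes`` genes, average within-module
    connectivity >= ``min_avg_connectivity`` and clustering coefficient >=
    ``min_cc``."""
    kept = []
    for mod in modules:
        module_statistics(mod, graph)
        if (
            mod.n_nodes >= min_nodes
            and mod.avg_connectivity >= min_avg_connectivity
            and mod.clustering_coefficient >= min_cc
        ):
            kept.append(mod)
    return kept
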