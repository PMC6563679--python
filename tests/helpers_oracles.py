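"""Independent oracles shared by the unit and acceptance tests.

These deliberately avoid the implementation paths they check: core numbers by
naive peeling, densest subgraph by Goldberg's max-flow construction, and a
direct two-group log-rank statistic.
"""

import networkx as nx
import numpy as np


def brute_force_core_numbers(graph: nx.Graph) -> dict:
    """Iterative-peel oracle for k-core numbers."""
    core = {}
    remaining = nx.Graph(graph)
    k = 0
    while remaining.number_of_nodes():
        peeled = True
        while peeled:
            peeled = False
            for v in list(remaining.nodes()):
                if remaining.degree(v) <= k:
                    core[v] = k
                    remaining.remove_node(v)
                    peeled = True
        k += 1
    return core


def densest_subgraph_exact(graph: nx.Graph) -> tuple[float, set]:
    """Exact maximum-average-degree subgraph via Goldberg's max-flow
    construction with binary search on the density guess."""
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    if m == 0:
        return 0.0, set()
    degrees = dict(graph.degree())
    lo, hi = 0.0, float(m)
    best = set(graph.nodes())
    eps = 1.0 / (n * (n - 1))  # granularity of 2E/N over subgraphs
    while hi - lo >= eps:
        g = (lo + hi) / 2.0
        flow = nx.DiGraph()
        for u, v in graph.edges():
            flow.add_edge(u, v, capacity=1.0)
            flow.add_edge(v, u, capacity=1.0)
        for v in graph.nodes():
            flow.add_edge("__s__", v, capacity=float(m))
            flow.add_edge(v, "__t__", capacity=m + 2 * g - degrees[v])
        _, (s_side, _) = nx.minimum_cut(flow, "__s__", "__t__")
        chosen = set(s_side) - {"__s__"}
        if chosen:
            lo = g
            best = chosen
        else:
            hi = g
    sub = graph.subgraph(best)
    return 2.0 * sub.number_of_edges() / len(best), best


def logrank_statistic(times, events, is_b) -> float:
    """Two-group log-rank chi-square with hypergeometric variance, written
    directly from the O-E table definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    is_b = np.asarray(is_b, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n_b = (at_risk & is_b).sum()
        d = (events & (times == t)).sum()
        d_b = (events & (times == t) & is_b).sum()
        o_minus_e += d_b - d * n_b / n
        if n > 1:
            var += d * (n_b / n) * (1 - n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
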