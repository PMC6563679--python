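"""Phenotype-specific Pearson co-expression networks and the differential
co-expression criterion.

Every unordered gene pair is scored in both phenotypes with the Pearson
correlation and its two-sided p-value; p-values are Benjamini-Hochberg
adjusted across all scored pairs within a phenotype. A pair is co-expressed
in a phenotype if ``|r| >= r_min`` (default 0.80) and adjusted ``p <= p_max``
(default 0.05). The differential ratio

    D = |(r_noninv - r_inv) / r_inv|

measures the relative change of the pair's correlation between phenotypes; a
pair is differentially co-expressed if ``D >= 1``. The phenotype network
(invasive: ICON, non-invasive: NICON) contains the pairs that are both
co-expressed in that phenotype and differentially co-expressed.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import benjamini_hochberg

__all__ = [
    "correlation_with_p",
    "phenotype_edges",
    "score_edge_candidates",
    "differential_filter",
    "build_network",
    "topology_metrics",
    "network_summary",
    "hub_genes",
]

INVASIVE = "invasive"
NONINVASIVE = "non-invasive"


def correlation_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation and its two-sided p-value from the exact t
    transform ``t = r * sqrt((n-2)/(1-r^2))`` on ``n - 2`` degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance vector: correlation undefined")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    p = _corr_pvalue(np.array([r]), n)[0]
    return r, float(p)


def _corr_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return p


def _pairwise(matrix: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle index pairs with correlations over rows of ``matrix``."""
    values = matrix.to_numpy(dtype=float)
    ia, ib = np.triu_indices(values.shape[0], k=1)
    sd = values.std(axis=1)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        warnings.warn(
            f"{degenerate.size} zero-variance gene(s) excluded from "
            "correlation scoring",
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(values)
    r = corr[ia, ib]
    return ia, ib, r


def phenotype_edges(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    phenotype: str,
    r_min: float = 0.80,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Score all unordered gene pairs within one phenotype's samples.

    Returns one row per scored pair (zero-variance genes excluded) with
    columns ``gene_a``, ``gene_b`` (canonical order ``gene_a < gene_b``),
    ``r``, ``p``, ``adj_p`` and the boolean ``coexpressed`` flag.
    """
    cols = metadata.index[metadata["phenotype"] == phenotype]
    cols = [c for c in matrix.columns if c in set(cols)]
    if len(cols) < 4:
        raise ValueError(f"phenotype {phenotype!r} has fewer than 4 samples")
    if matrix.shape[0] < 2:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "r", "p", "adj_p", "coexpressed"]
        )
    sub = matrix[cols]
    ia, ib, r = _pairwise(sub)
    valid = np.isfinite(r)
    ia, ib, r = ia[valid], ib[valid], r[valid]
    p = _corr_pvalue(r, len(cols))
    adj_p = benjamini_hochberg(p)
    genes = matrix.index.to_numpy()
    ga, gb = genes[ia], genes[ib]
    swap = ga > gb
    ga[swap], gb[swap] = gb[swap], ga[swap]
    return pd.DataFrame(
        {
            "gene_a": ga,
            "gene_b": gb,
            "r": r,
            "p": p,
            "adj_p": adj_p,
            "coexpressed": (np.abs(r) >= r_min) & (adj_p <= p_max),
        }
    )


def score_edge_candidates(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    r_min: float = 0.80,
    p_max: float = 0.05,
    invasive_label: str = INVASIVE,
    noninvasive_label: str = NONINVASIVE,
) -> pd.DataFrame:
    """Score every gene pair in both phenotypes and attach the differential
    ratio D. Only pairs scored in both phenotypes are kept."""
    inv = phenotype_edges(matrix, metadata, invasive_label, r_min, p_max)
    non = phenotype_edges(matrix, metadata, noninvasive_label, r_min, p_max)
    merged = inv.merge(
        non, on=["gene_a", "gene_b"], suffixes=("_inv", "_noninv"), how="inner"
    )
    return differential_filter(merged)


def differential_filter(edges: pd.DataFrame, d_min: float = 1.0) -> pd.DataFrame:
    """Attach the differential co-expression ratio D and its keep flag.

    ``D = |(r_noninv - r_inv) / r_inv|``; when ``r_inv`` is exactly zero the
    relative change is treated as infinite and the pair is kept.
    """
    edges = edges.copy()
    r_inv = edges["r_inv"].to_numpy(dtype=float)
    r_non = edges["r_noninv"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.abs((r_non - r_inv) / r_inv)
    d[r_inv == 0] = np.inf
    edges["D"] = d
    edges["differential"] = d >= d_min
    return edges


def build_network(candidates: pd.DataFrame, phenotype: str) -> nx.Graph:
    """Assemble one phenotype's differential co-expression network.

    An edge enters the network iff the pair is co-expressed in that phenotype
    and passes the differential filter; nodes are the endpoints of surviving
    edges.
    """
    if phenotype == INVASIVE:
        mask = candidates["coexpressed_inv"] & candidates["differential"]
    elif phenotype == NONINVASIVE:
        mask = candidates["coexpressed_noninv"] & candidates["differential"]
    else:
        raise ValueError(f"unknown phenotype {phenotype!r}")
    graph = nx.Graph(phenotype=phenotype)
    kept = candidates.loc[mask]
    for row in kept.itertuples(index=False):
        a, b = sorted((row.gene_a, row.gene_b))
        if a == b:
            continue
        graph.add_edge(
            a, b, r_inv=float(row.r_inv), r_noninv=float(row.r_noninv), D=float(row.D)
        )
    return graph


def topology_metrics(network: nx.Graph) -> pd.DataFrame:
    """Per-node degree, betweenness (unnormalized shortest-path), and local
    clustering coefficient."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    degree = dict(network.degree())
    betweenness = nx.betweenness_centrality(network, normalized=False)
    clustering = nx.clustering(network)
    nodes = sorted(network.nodes())
    return pd.DataFrame(
        {
            "degree": [degree[v] for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )


def network_summary(network: nx.Graph) -> dict:
    """Network-level statistics: size, clustering coefficient (mean of local
    coefficients over nodes with degree >= 2), and Freeman degree
    centralization ``sum_v(d_max - d_v) / ((N - 1)(N - 2))``."""
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    degrees = np.array([d for _, d in network.degree()], dtype=float)
    local = nx.clustering(network)
    eligible = [v for v in network if network.degree(v) >= 2]
    cc = float(np.mean([local[v] for v in eligible])) if eligible else 0.0
    centralization = (
        float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2))) if n >= 3 else None
    )
    return {
        "n_nodes": n,
        "n_edges": network.number_of_edges(),
        "clustering_coefficient": cc,
        "degree_centralization": centralization,
    }


def hub_genes(network: nx.Graph, k: int = 8) -> list[str]:
    """Top-k hub genes ranked by degree, ties broken by betweenness, then by
    gene id. If k exceeds the node count every node is returned."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    metrics = topology_metrics(network)
    ranked = metrics.sort_values(
        by=["degree", "betweenness", "gene"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return list(ranked.index[:k])
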