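"""Core-module refinement and unsupervised subtype discrimination.

Selected modules are merged and their co-expression pattern is recomputed at
a tightened correlation cutoff (0.80 -> 0.90 by default) in the phenotype
where the modules are active; the genes of the largest connected component of
the surviving edges form the *core module* — the minimal gene set retaining
the modules' discrimination ability. Discrimination is quantified by
projecting samples onto principal components of the core genes' expression
and scoring the separation of known phenotype labels with the mean silhouette
coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .coexnet import NONINVASIVE, differential_filter, phenotype_edges

__all__ = [
    "CoreModule",
    "SubtypeProjection",
    "refine_core",
    "pca_project",
    "separation_score",
]


@dataclass
class CoreModule:
    members: list[str]
    source_modules: list[str]
    pcc_cutoff: float
    edges: pd.DataFrame  # surviving edge list with per-phenotype correlations

    @property
    def is_empty(self) -> bool:
        return len(self.members) == 0


@dataclass
class SubtypeProjection:
    """PCA scores of samples in the space of a gene set's expression."""

    scores: pd.DataFrame  # samples x components, columns PC1..PCm
    variance_ratio: np.ndarray  # fraction of total variance per component
    n_retained: int  # minimal prefix reaching the variance threshold
    var_threshold: float

    @property
    def retained_scores(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_retained]


def refine_core(
    module_union: set[str] | list[str],
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    r_min: float = 0.90,
    p_max: float = 0.05,
    d_min: float = 1.0,
    phenotype: str = NONINVASIVE,
    source_modules: list[str] | None = None,
) -> CoreModule:
    """Tighten the co-expression cutoff over the merged module genes.

    Pairwise correlations among the union genes are recomputed per phenotype;
    edges with ``|r| >= r_min`` (adjusted ``p <= p_max``) in the active
    phenotype that still satisfy the differential criterion survive, and the
    core module is the largest connected component of the surviving edge set
    (ties broken by the lexicographically smallest member).
    """
    union = sorted(set(module_union))
    if not union:
        raise ValueError("module union is empty")
    sub = matrix.loc[[g for g in matrix.index if g in set(union)]]
    phenos = sorted(metadata["phenotype"].unique())
    if len(phenos) < 2:
        raise ValueError("both phenotypes must be present")
    inv_label = [p for p in phenos if p != phenotype]
    if phenotype not in phenos or not inv_label:
        raise ValueError(f"phenotype {phenotype!r} not found in metadata")

    active = phenotype_edges(sub, metadata, phenotype, r_min=r_min, p_max=p_max)
    other = phenotype_edges(sub, metadata, inv_label[0], r_min=r_min, p_max=p_max)
    if phenotype == NONINVASIVE:
        merged = other.merge(
            active, on=["gene_a", "gene_b"], suffixes=("_inv", "_noninv"), how="inner"
        )
        active_flag = "coexpressed_noninv"
    else:
        merged = active.merge(
            other, on=["gene_a", "gene_b"], suffixes=("_inv", "_noninv"), how="inner"
        )
        active_flag = "coexpressed_inv"
    merged = differential_filter(merged, d_min=d_min)
    surviving = merged.loc[merged[active_flag] & merged["differential"]]

    if surviving.empty:
        warnings.warn("no edges survive the tightened cutoff; core module is empty")
        return CoreModule([], source_modules or [], r_min, surviving)

    graph = nx.Graph()
    graph.add_edges_from(zip(surviving["gene_a"], surviving["gene_b"]))
    comps = sorted(
        nx.connected_components(graph), key=lambda c: (-len(c), min(map(str, c)))
    )
    members = sorted(comps[0])
    keep = surviving[
        surviving["gene_a"].isin(members) & surviving["gene_b"].isin(members)
    ].reset_index(drop=True)
    return CoreModule(members, source_modules or [], r_min, keep)


def pca_project(
    matrix: pd.DataFrame, var_threshold: float = 0.85
) -> SubtypeProjection:
    """PCA of samples in the space of the (per-gene centered) expression of a
    gene set.

    Components are ordered by eigenvalue; each component's sign is fixed so
    that its largest-magnitude gene loading is positive; the retained prefix
    is the smallest one whose cumulative variance fraction reaches
    ``var_threshold``.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 3:
        raise ValueError("need at least 2 genes and 3 samples")
    centered = matrix.sub(matrix.mean(axis=1), axis=0)
    x = centered.to_numpy(dtype=float).T  # samples x genes
    if not np.any(x):
        raise ValueError("zero total variance")
    n_comp = min(x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(x)
    # sign convention: largest-|loading| positive per component
    for j in range(n_comp):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    n_retained = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    n_retained = min(n_retained, n_comp)
    return SubtypeProjection(
        scores=pd.DataFrame(
            scores,
            index=matrix.columns.rename("sample_id"),
            columns=[f"PC{j + 1}" for j in range(n_comp)],
        ),
        variance_ratio=ratio,
        n_retained=n_retained,
        var_threshold=var_threshold,
    )


def separation_score(projection: SubtypeProjection, labels: pd.Series) -> float:
    """Mean silhouette coefficient of the given labels in retained-PC space
    (Euclidean distance). Samples in singleton classes score 0."""
    x = projection.retained_scores.to_numpy(dtype=float)
    y = labels.loc[projection.scores.index].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 label classes")
    # pairwise distances; n is small (samples), O(n^2) is fine
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    sil = np.zeros(len(y))
    for i in range(len(y)):
        same = (y == y[i]) & (np.arange(len(y)) != i)
        if not same.any():
            sil[i] = 0.0  # singleton class
            continue
        a = d[i, same].mean()
        b = min(d[i, y == c].mean() for c in classes if c != y[i])
        sil[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
    return float(sil.mean())
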