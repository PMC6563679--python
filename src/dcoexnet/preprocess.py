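"""Normalization, duplicate-probe collapse, and differential expression.

The differential-expression test runs on ``log2(x + 1)`` values while fold
changes are reported on the linear scale as ``mean(case) / mean(control)``,
so that the 10%-change gates (FC < 0.9 down, FC > 1.1 up) act on linear
ratios. Two test variants are provided: a Welch two-sample t-test and a
moderated t-test that shrinks per-gene sample variances toward a pooled prior
by empirical Bayes, with the prior degrees of freedom and scale estimated
from the observed variances by matching moments of the log variances.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "quantile_normalize",
    "collapse_duplicates",
    "differential_expression",
    "benjamini_hochberg",
]

_VAR_FLOOR = 1e-12


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common distribution given by the
    across-sample mean of order statistics.

    Ties within a sample receive the mean of their tied quantile values
    (average ranks interpolated on the reference distribution), so the rank
    order within each sample is preserved.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if matrix.size == 0:
        raise ValueError("empty expression matrix")
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    grid = np.arange(values.shape[0], dtype=float)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_duplicates(
    matrix: pd.DataFrame, gene_map: Mapping[str, str]
) -> pd.DataFrame:
    """Average rows that map to the same gene symbol.

    ``gene_map`` maps measurement (probe) ids to gene symbols; measurement
    ids absent from the map are retained under their own id, since
    unannotated probes can still carry signal downstream.
    """
    if not gene_map:
        return matrix.copy()
    symbols = pd.Index([gene_map.get(pid, pid) for pid in matrix.index], name="gene")
    collapsed = matrix.groupby(symbols, sort=False).mean()
    return collapsed


def benjamini_hochberg(p_values: np.ndarray | pd.Series | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _moderated_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate the inverse-chi-square prior (d0, s0^2) for gene variances.

    Moment matching on log variances: if s^2 ~ s0^2 * F(df, d0) then
    e = log(s^2) - digamma(df/2) + log(df/2) has mean log(s0^2) +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2) beyond the
    sampling term trigamma(df/2).
    """
    z = np.log(np.maximum(s2, _VAR_FLOOR))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) if e.size > 1 else 0.0
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # no excess variability: variances are exchangeable, prior df infinite
        # and the prior scale is the plain mean of the sample variances
        return np.inf, float(np.mean(np.maximum(s2, _VAR_FLOOR)))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def differential_expression(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    method: str = "moderated_t",
    case: str = "invasive",
    p_threshold: float = 0.05,
    fc_up: float = 1.1,
    fc_down: float = 0.9,
) -> pd.DataFrame:
    """Per-gene two-group differential expression.

    Returns a DataFrame indexed by gene with columns ``fc`` (linear-scale
    ratio of case over control group means), ``p``, ``adj_p``
    (Benjamini-Hochberg), and ``direction`` in {"up", "down", "none"}: a gene
    is "up" iff adj_p < p_threshold and fc > fc_up, "down" iff adj_p <
    p_threshold and fc < fc_down.
    """
    if method not in {"moderated_t", "welch_t"}:
        raise ValueError(f"unknown method {method!r}")
    phenotypes = metadata.loc[matrix.columns, "phenotype"]
    case_mask = (phenotypes == case).to_numpy()
    n1, n2 = int(case_mask.sum()), int((~case_mask).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")

    linear = matrix.to_numpy(dtype=float)
    fc = linear[:, case_mask].mean(axis=1) / linear[:, ~case_mask].mean(axis=1)

    logged = np.log2(linear + 1.0)
    x1, x2 = logged[:, case_mask], logged[:, ~case_mask]
    diff = x1.mean(axis=1) - x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)

    if method == "welch_t":
        v1f, v2f = np.maximum(v1, _VAR_FLOOR), np.maximum(v2, _VAR_FLOOR)
        se2 = v1f / n1 + v2f / n2
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1f / n1) ** 2 / (n1 - 1) + (v2f / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
        p[(v1 + v2 == 0) & (diff == 0)] = 1.0
    else:
        df_resid = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
        d0, s0_sq = _moderated_variance_prior(s2, df_resid)
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        # total df capped at the pooled residual df across genes
        df_total = min(d0 + df_resid, len(s2) * df_resid)
        t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    adj_p = benjamini_hochberg(p)
    direction = np.where(
        (adj_p < p_threshold) & (fc > fc_up),
        "up",
        np.where((adj_p < p_threshold) & (fc < fc_down), "down", "none"),
    )
    return pd.DataFrame(
        {"fc": fc, "p": p, "adj_p": adj_p, "direction": direction},
        index=matrix.index.rename("gene"),
    )
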