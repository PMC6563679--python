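"""Patient clustering on module expression and survival-based prognosis.

Samples are clustered by k-means on their leading principal-component scores
(three clusters on the first three components by default). Survival
differences between groups are assessed with the Kaplan-Meier product-limit
estimator, the k-sample log-rank test, and Cox proportional-hazards
regression (Efron tie handling); the *extreme-cluster* hazard ratio
contrasts the clusters with the lowest and highest mean PC1 score. For
signature-based validation, a multivariate Cox fit over the signature genes
yields a per-sample prognostic index (the Cox linear predictor) whose median
splits the cohort into low- and high-risk groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.cluster import KMeans

from .coremod import SubtypeProjection

__all__ = [
    "CoxResult",
    "PrognosisResult",
    "cluster_patients",
    "kaplan_meier",
    "log_rank_test",
    "cox_ph",
    "extreme_cluster_hr",
    "signature_risk_assessment",
    "marker_group_test",
]


@dataclass
class CoxResult:
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    flagged: bool = False  # convergence trouble / separation


@dataclass
class PrognosisResult:
    labels: pd.Series
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    cox: CoxResult | None


def cluster_patients(
    projection: SubtypeProjection,
    k: int = 3,
    n_components: int = 3,
    seed: int = 0,
) -> pd.Series:
    """k-means cluster labels from the first ``n_components`` PC scores.

    Runs 25 restarts and keeps the best inertia; clusters are relabeled
    0..k-1 in increasing order of their mean PC1 score, so label 0 is the
    cluster with the lowest PC1 loadings.
    """
    scores = projection.scores
    if k > len(scores):
        raise ValueError("more clusters than samples")
    x = scores.iloc[:, : min(n_components, scores.shape[1])].to_numpy(dtype=float)
    km = KMeans(n_clusters=k, n_init=25, random_state=seed)
    raw = km.fit_predict(x)
    pc1_means = pd.Series(scores.iloc[:, 0].to_numpy()).groupby(raw).mean()
    order = {old: new for new, old in enumerate(pc1_means.sort_values().index)}
    labels = pd.Series([order[r] for r in raw], index=scores.index, name="cluster")
    return labels


def kaplan_meier(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival curve; columns ``time`` and ``survival``.

    ``records`` needs columns ``time`` and ``event``. Censored subjects leave
    the risk set after their recorded time.
    """
    if len(records) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"].astype(bool))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def log_rank_test(records: pd.DataFrame) -> tuple[float, float]:
    """k-sample log-rank test over the ``group`` column; returns the
    chi-square statistic ((groups - 1) df) and its p-value."""
    groups = records["group"]
    if groups.nunique() < 2:
        raise ValueError("need at least 2 groups")
    if not records["event"].astype(bool).any():
        raise ValueError("need at least one event")
    res = multivariate_logrank_test(
        records["time"], groups, records["event"].astype(bool)
    )
    return float(res.test_statistic), float(res.p_value)


def cox_ph(records: pd.DataFrame, covariate: str | pd.Series) -> CoxResult:
    """Univariate Cox proportional-hazards fit (Efron ties, Newton solver).

    ``covariate`` is either a column name of ``records`` or a Series aligned
    on its index. Returns beta, HR = exp(beta), the 95% Wald CI on the HR,
    and the Wald p-value. Monotone likelihood (complete separation) is
    reported via the ``flagged`` field with a capped coefficient.
    """
    df = records[["time", "event"]].copy()
    df["event"] = df["event"].astype(bool)
    if isinstance(covariate, str):
        df["x"] = records[covariate].to_numpy(dtype=float)
    else:
        df["x"] = covariate.loc[records.index].to_numpy(dtype=float)
    if df["x"].nunique() < 2:
        raise ValueError("constant covariate")
    if not df["event"].any():
        raise ValueError("need at least one event")
    cph = CoxPHFitter()
    flagged = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        flagged = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="time", event_col="event")
    beta = float(cph.params_["x"])
    if abs(beta) > 20:  # monotone likelihood: cap and flag
        flagged = True
        beta = float(np.clip(beta, -20, 20))
    se = float(cph.standard_errors_["x"])
    return CoxResult(
        beta=beta,
        hr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        p=float(cph.summary.loc["x", "p"]),
        flagged=flagged,
    )


def extreme_cluster_hr(
    records: pd.DataFrame, labels: pd.Series
) -> tuple[CoxResult, pd.DataFrame]:
    """Cox HR between the extreme clusters (lowest vs highest mean-PC1 label).

    ``labels`` are the ordered cluster labels from :func:`cluster_patients`;
    the contrast is label ``min`` (reference, highest-risk by construction
    sits at low PC1 in the motivating design) against label ``max``. Returns
    the Cox result and the two-cluster record subset.
    """
    lo, hi = int(labels.min()), int(labels.max())
    if lo == hi:
        raise ValueError("need at least two clusters")
    subset = records.loc[labels.isin([lo, hi]).reindex(records.index, fill_value=False)]
    indicator = (labels.loc[subset.index] == lo).astype(float)  # 1 = low-PC1 cluster
    result = cox_ph(subset, indicator)
    sub = subset.copy()
    sub["group"] = np.where(indicator == 1.0, f"cluster{lo}", f"cluster{hi}")
    return result, sub


def signature_risk_assessment(
    matrix: pd.DataFrame,
    gene_set: list[str] | set[str],
    records: pd.DataFrame,
    split: str = "median",
    coefficients: dict[str, float] | None = None,
) -> PrognosisResult:
    """Prognostic-index risk split over a gene signature.

    A multivariate Cox model over the signature genes (log2-transformed,
    standardized expression) gives each sample the prognostic index
    ``sum_g beta_g * x_g``; samples at or below the ``median`` index form the
    low-risk group. KM curves, the log-rank test, and a two-group Cox HR
    (high vs low) are computed on the split. Genes absent from the matrix are
    reported via a warning and skipped.

    When ``coefficients`` (gene -> Cox beta) are supplied — e.g. weights
    learned on a training cohort — the in-cohort Cox fit is skipped and the
    index uses the given weights. Note that when the weights are fit on the
    same cohort that is then split, the downstream log-rank and HR inference
    is optimistic (the fit and the test share the same noise); calibrated
    inference requires prespecified weights.
    """
    if split != "median":
        raise ValueError("only the median split is provided")
    genes = sorted(set(gene_set))
    present = [g for g in genes if g in matrix.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) absent, skipped: {missing}")
    if len(present) < 2:
        raise ValueError("fewer than 2 signature genes present")

    x = np.log2(matrix.loc[present, records.index].to_numpy(dtype=float).T + 1.0)
    x = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    if coefficients is None:
        df = pd.DataFrame(x, index=records.index, columns=present)
        df["time"] = records["time"]
        df["event"] = records["event"].astype(bool)
        cph = CoxPHFitter(penalizer=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        betas = cph.params_[present].to_numpy()
    else:
        betas = np.array([coefficients.get(g, 0.0) for g in present])
    index = pd.Series(x @ betas, index=records.index, name="prognostic_index")
    risk = pd.Series(
        np.where(index > index.median(), "high", "low"), index=records.index, name="risk"
    )
    if risk.value_counts().min() < 2:
        raise ValueError("degenerate risk split: a group has fewer than 2 samples")

    grouped = records.copy()
    grouped["group"] = risk
    chi2, p = log_rank_test(grouped)
    cox = cox_ph(grouped, (risk == "high").astype(float))
    curves = {
        label: kaplan_meier(grouped.loc[grouped["group"] == label])
        for label in ("low", "high")
    }
    return PrognosisResult(
        labels=risk, km_curves=curves, logrank_chi2=chi2, logrank_p=p, cox=cox
    )


def marker_group_test(
    matrix: pd.DataFrame, metadata: pd.DataFrame, gene_id: str
) -> dict:
    """Two-sided two-sample t-test (pooled variance) of one gene's expression
    between the phenotype groups, with group means and standard errors."""
    if gene_id not in matrix.index:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    phenos = metadata.loc[matrix.columns, "phenotype"]
    out: dict = {"gene": gene_id}
    values = {}
    for ph in sorted(phenos.unique()):
        v = matrix.loc[gene_id, phenos.index[phenos == ph]].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"group {ph!r} has fewer than 2 samples")
        values[ph] = v
        out[ph] = {"mean": float(v.mean()), "se": float(stats.sem(v))}
    if len(values) != 2:
        raise ValueError("need exactly 2 phenotype groups")
    a, b = values.values()
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if a.var(ddof=1) + b.var(ddof=1) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    out["t"], out["p"] = float(t), float(p)
    return out
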