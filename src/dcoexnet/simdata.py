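"""Synthetic two-phenotype expression data with planted differential co-expression.

Generates gene x sample intensity matrices that emulate a two-group tumor
microarray cohort: a configurable number of genes, an invasive and a
non-invasive sample group, planted gene blocks whose within-block correlation
differs between the phenotypes, planted differentially expressed genes (DEGs)
with multiplicative fold-change effects, and per-sample survival outcomes
(follow-up time plus event flag) whose hazard depends on a latent risk group.

Planted correlation blocks use a shared latent factor: within a block and a
phenotype, each gene's latent value is ``sqrt(r) * z_block + sqrt(1-r) * eps``
with ``z_block`` shared across the block, which yields exact compound symmetry
with pairwise correlation ``r``. Intensities are exponentiated from the
Gaussian latent so they are strictly positive and fold changes act
multiplicatively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedBlock",
    "SimConfig",
    "GroundTruth",
    "generate_expression",
    "generate_survival",
    "generate_dataset",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class PlantedBlock:
    """A gene block co-expressed at ``r_noninv`` in non-invasive samples and
    ``r_inv`` in invasive samples."""

    size: int
    r_noninv: float
    r_inv: float


@dataclass
class SimConfig:
    """Parameters of the simulated cohort.

    Defaults mirror the study design being emulated: 22 invasive vs 18
    non-invasive samples, follow-up between 3 and 10.5 years, and a gene count
    that is a scaled-down stand-in for a ~30k-gene array.
    """

    n_genes: int = 2000
    n_invasive: int = 22
    n_noninvasive: int = 18
    planted_modules: Sequence[PlantedBlock] = field(default_factory=tuple)
    deg_fraction: float = 0.0
    fc_effect: float = 1.5
    noise_sd: float = 0.3
    followup_range: tuple[float, float] = (3.0, 10.5)
    true_hr: float = 1.0
    event_rate_baseline: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.planted_modules = tuple(
            b if isinstance(b, PlantedBlock) else PlantedBlock(*b)
            for b in self.planted_modules
        )
        if self.n_invasive < 3 or self.n_noninvasive < 3:
            raise ValueError("each phenotype group needs at least 3 samples")
        if sum(b.size for b in self.planted_modules) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")
        for b in self.planted_modules:
            if b.size < 2:
                raise ValueError("planted blocks need at least 2 genes")
            for r in (b.r_noninv, b.r_inv):
                if not -1.0 < r < 1.0:
                    raise ValueError(f"block correlation {r} outside (-1, 1)")
                if r < 0 and r < -1.0 / (b.size - 1):
                    # compound symmetry is positive definite only above -1/(m-1)
                    raise ValueError(
                        f"correlation {r} with block size {b.size} implies a "
                        "non-positive-definite covariance"
                    )
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must be in [0, 1]")
        if self.fc_effect <= 0:
            raise ValueError("fc_effect must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.followup_range
        if not 0 < lo < hi:
            raise ValueError("followup_range must satisfy 0 < min < max")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if self.event_rate_baseline < 0:
            raise ValueError("event_rate_baseline must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: DEG ids with direction, module memberships, latent
    per-sample risk labels, and the true hazard ratio."""

    planted_deg_ids: dict[str, str]
    planted_module_members: list[set[str]]
    risk_labels: pd.Series
    true_hr: float


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _block_latent(
    rng: np.random.Generator, size: int, n_samples: int, r: float
) -> np.ndarray:
    """Standard-normal latent matrix (size x n_samples) with exact compound
    symmetry at correlation r."""
    if r >= 0:
        z = rng.standard_normal(n_samples)
        eps = rng.standard_normal((size, n_samples))
        return np.sqrt(r) * z + np.sqrt(1.0 - r) * eps
    # negative r: fall back to an explicit Cholesky draw (valid for r > -1/(m-1))
    cov = np.full((size, size), r)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((size, n_samples))


def generate_expression(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate an expression matrix with its sample metadata and ground truth.

    Returns
    -------
    expression : DataFrame, genes x samples, strictly positive intensities.
    metadata : DataFrame indexed by sample id with columns ``phenotype``,
        ``grade``, ``followup_years``, ``event``.
    truth : GroundTruth
    """
    rng_expr, rng_surv = _rng_streams(config.seed, 2)

    n_inv, n_non = config.n_invasive, config.n_noninvasive
    n_samples = n_inv + n_non
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    sample_ids = [f"INV{i + 1:03d}" for i in range(n_inv)] + [
        f"NON{i + 1:03d}" for i in range(n_non)
    ]
    invasive_mask = np.array([True] * n_inv + [False] * n_non)

    # per-gene baseline log intensity, shared across samples and phenotypes
    base = rng_expr.uniform(np.log(50.0), np.log(500.0), size=config.n_genes)
    latent = rng_expr.standard_normal((config.n_genes, n_samples))

    # overwrite planted blocks (assigned to leading gene indices) with
    # phenotype-specific compound-symmetry draws
    module_members: list[set[str]] = []
    pos = 0
    for block in config.planted_modules:
        rows = slice(pos, pos + block.size)
        latent[rows, invasive_mask] = _block_latent(
            rng_expr, block.size, n_inv, block.r_inv
        )
        latent[rows, ~invasive_mask] = _block_latent(
            rng_expr, block.size, n_non, block.r_noninv
        )
        module_members.append(set(gene_ids[pos : pos + block.size]))
        pos += block.size

    log_values = base[:, None] + config.noise_sd * latent

    # planted DEGs: leading genes, so that planted blocks are covered first;
    # block genes are down-regulated in the invasive group (the planted
    # modules are active in the non-invasive phenotype), the rest alternate
    n_deg = int(round(config.deg_fraction * config.n_genes))
    deg_ids: dict[str, str] = {}
    n_blockgenes = pos
    log_fc = np.log(config.fc_effect)
    for i in range(n_deg):
        if i < n_blockgenes:
            direction = "down"
        else:
            direction = "up" if (i - n_blockgenes) % 2 == 0 else "down"
        deg_ids[gene_ids[i]] = direction
        shift = log_fc if direction == "up" else -log_fc
        log_values[i, invasive_mask] += shift

    expression = pd.DataFrame(np.exp(log_values), index=gene_ids, columns=sample_ids)
    expression.index.name = "gene"

    risk_labels = pd.Series(
        np.where(invasive_mask, "high", "low"), index=sample_ids, name="risk"
    )
    survival = generate_survival(risk_labels, config, rng=rng_surv)

    metadata = pd.DataFrame(
        {
            "phenotype": np.where(invasive_mask, "invasive", "non-invasive"),
            # grade tracks the latent risk group: high-risk tumors are grade IV
            "grade": np.where(invasive_mask, "IV", "II"),
            "followup_years": survival["time"].to_numpy(),
            "event": survival["event"].to_numpy(),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = GroundTruth(
        planted_deg_ids=deg_ids,
        planted_module_members=module_members,
        risk_labels=risk_labels,
        true_hr=config.true_hr,
    )
    return expression, metadata, truth


def generate_survival(
    risk_labels: pd.Series,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate follow-up records for the given latent risk labels.

    Event times are exponential with hazard
    ``event_rate_baseline * true_hr**(risk == "high")``; administrative
    censoring times are uniform over ``followup_range``; the recorded time is
    the smaller of the two and the event flag marks whether the event came
    first.
    """
    if config.true_hr <= 0:
        raise ValueError("true_hr must be positive")
    if rng is None:
        rng = _rng_streams(config.seed, 2)[1]
    n = len(risk_labels)
    hazard = config.event_rate_baseline * np.where(
        risk_labels.to_numpy() == "high", config.true_hr, 1.0
    )
    with np.errstate(divide="ignore"):
        event_time = np.where(
            hazard > 0, rng.exponential(1.0, size=n) / np.maximum(hazard, 1e-300), np.inf
        )
    censor_time = rng.uniform(*config.followup_range, size=n)
    observed = np.minimum(event_time, censor_time)
    return pd.DataFrame(
        {
            "time": observed,
            "event": event_time <= censor_time,
            "group": risk_labels.to_numpy(),
        },
        index=risk_labels.index.rename("sample_id"),
    )


def generate_dataset(
    config: SimConfig, outdir: str | Path
) -> tuple[Path, Path, Path]:
    """Generate and write expression TSV, metadata TSV, and ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expression, metadata, truth = generate_expression(config)
    expr_path = outdir / "expression.tsv"
    meta_path = outdir / "metadata.tsv"
    truth_path = outdir / "ground_truth.json"
    expression.to_csv(expr_path, sep="\t")
    metadata.to_csv(meta_path, sep="\t")
    write_ground_truth(truth, truth_path)
    return expr_path, meta_path, truth_path


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "planted_deg_ids": truth.planted_deg_ids,
        "planted_module_members": [sorted(m) for m in truth.planted_module_members],
        "risk_labels": truth.risk_labels.to_dict(),
        "true_hr": truth.true_hr,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        planted_deg_ids=payload["planted_deg_ids"],
        planted_module_members=[set(m) for m in payload["planted_module_members"]],
        risk_labels=pd.Series(payload["risk_labels"], name="risk"),
        true_hr=payload["true_hr"],
    )
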