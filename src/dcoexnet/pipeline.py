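"""End-to-end orchestration: normalize -> DEGs -> differential co-expression
networks -> MCODE modules -> core module -> subtype clustering and prognosis
(-> enrichment when a GMT collection is supplied).

Every stage's artifacts are written under the output directory and the run is
fully determined by (inputs, configuration, seed).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import coexnet, coremod, enrich, io, moddetect, preprocess, prognosis
from .config import PipelineConfig

__all__ = ["StageError", "run_pipeline"]

logger = logging.getLogger("dcoexnet")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception | str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - halt with stage context
                raise StageError(name, exc) from exc

        return inner

    return wrap


def run_pipeline(
    config: PipelineConfig,
    expression_path: str | Path,
    metadata_path: str | Path,
    outdir: str | Path,
    gene_map: Mapping[str, str] | None = None,
    gmt_path: str | Path | None = None,
) -> dict:
    """Run the full analysis; returns the result bundle and writes every
    intermediate artifact under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    bundle: dict = {"config": config.to_dict()}

    matrix, metadata = _load(expression_path, metadata_path)
    normalized = _normalize(matrix, gene_map, config, outdir)
    deg_table, deg_genes = _deg(normalized, metadata, config, outdir)
    candidates, networks = _networks(normalized, deg_genes, metadata, config, outdir)
    modules = _modules(networks, config, outdir)
    core = _core(modules, normalized, metadata, config, outdir)
    bundle["deg"] = {
        "n_genes_tested": len(deg_table),
        "n_deg": len(deg_genes),
        "n_up": int((deg_table["direction"] == "up").sum()),
        "n_down": int((deg_table["direction"] == "down").sum()),
    }
    bundle["networks"] = {
        name: coexnet.network_summary(g) if g.number_of_nodes() else
        {"n_nodes": 0, "n_edges": 0, "clustering_coefficient": None,
         "degree_centralization": None}
        for name, g in networks.items()
    }
    bundle["n_candidate_pairs"] = len(candidates)
    bundle["modules"] = {
        m.module_id: {
            "n_nodes": m.n_nodes,
            "avg_connectivity": m.avg_connectivity,
            "clustering_coefficient": m.clustering_coefficient,
            "members": sorted(m.members),
        }
        for m in modules
    }
    bundle["core_module"] = {
        "members": core.members,
        "pcc_cutoff": core.pcc_cutoff,
        "n_genes": len(core.members),
    }

    if core.members:
        bundle["prognosis"] = _prognosis(core, normalized, metadata, config, outdir)
    else:
        bundle["prognosis"] = None
        logger.warning("core module empty; prognosis stage skipped")

    if gmt_path is not None:
        bundle["enrichment"] = _enrichment(
            core, deg_genes, normalized, gmt_path, config, outdir
        )

    io.write_json(bundle, outdir / "bundle.json")
    return bundle


@_stage("load")
def _load(expression_path, metadata_path):
    matrix = io.read_expression(expression_path)
    metadata = io.read_metadata(metadata_path)
    missing = [c for c in matrix.columns if c not in metadata.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")
    return matrix, metadata.loc[matrix.columns]


@_stage("normalize")
def _normalize(matrix, gene_map, config, outdir):
    normalized = preprocess.quantile_normalize(matrix)
    if gene_map:
        normalized = preprocess.collapse_duplicates(normalized, gene_map)
    io.write_expression(normalized, outdir / "normalized.tsv")
    logger.info("normalized %d genes x %d samples", *normalized.shape)
    return normalized


@_stage("deg")
def _deg(matrix, metadata, config, outdir):
    table = preprocess.differential_expression(
        matrix,
        metadata,
        method=config.deg_method,
        case=config.case_phenotype,
        p_threshold=config.deg_p,
        fc_up=config.fc_up,
        fc_down=config.fc_down,
    )
    table.to_csv(outdir / "deg.tsv", sep="\t")
    deg_genes = list(table.index[table["direction"] != "none"])
    logger.info("DEG stage: %d of %d genes called", len(deg_genes), len(table))
    if len(deg_genes) < 2:
        raise ValueError("fewer than 2 DEGs; no network can be built")
    return table, deg_genes


@_stage("network")
def _networks(matrix, deg_genes, metadata, config, outdir):
    candidates = coexnet.score_edge_candidates(
        matrix.loc[deg_genes],
        metadata,
        r_min=config.r_min,
        p_max=config.edge_p_max,
    )
    candidates = coexnet.differential_filter(candidates, d_min=config.d_min)
    io.write_edge_list(candidates, outdir / "edge_candidates.tsv")
    networks = {}
    for phenotype in (coexnet.INVASIVE, coexnet.NONINVASIVE):
        net = coexnet.build_network(candidates, phenotype)
        networks[phenotype] = net
        tag = "icon" if phenotype == coexnet.INVASIVE else "nicon"
        if net.number_of_nodes():
            io.write_graphml(net, outdir / f"{tag}.graphml")
            coexnet.topology_metrics(net).to_csv(
                outdir / f"{tag}_nodes.tsv", sep="\t"
            )
        logger.info(
            "%s: %d links among %d genes",
            tag.upper(),
            net.number_of_edges(),
            net.number_of_nodes(),
        )
    return candidates, networks


@_stage("modules")
def _modules(networks, config, outdir):
    net = networks[config.module_network]
    raw = moddetect.mcode_complexes(
        net, vwp=config.vwp, haircut=config.haircut, min_core=config.min_core
    )
    kept = moddetect.filter_modules(
        raw,
        net,
        min_nodes=config.min_module_nodes,
        min_avg_connectivity=config.min_avg_connectivity,
        min_cc=config.min_module_cc,
    )
    io.write_modules(kept, outdir / "modules.tsv")
    logger.info("modules: %d detected, %d pass filters", len(raw), len(kept))
    return kept


@_stage("core")
def _core(modules, matrix, metadata, config, outdir):
    selected = modules
    if config.core_modules is not None:
        wanted = set(config.core_modules)
        selected = [m for m in modules if m.module_id in wanted]
    union = set().union(*(m.members for m in selected)) if selected else set()
    if not union:
        logger.warning("no modules to merge; core module is empty")
        return coremod.CoreModule([], [], config.core_r_min, pd.DataFrame())
    core = coremod.refine_core(
        union,
        matrix,
        metadata,
        r_min=config.core_r_min,
        p_max=config.edge_p_max,
        d_min=config.d_min,
        phenotype=config.module_network,
        source_modules=[m.module_id for m in selected],
    )
    io.write_json(
        {
            "members": core.members,
            "source_modules": core.source_modules,
            "pcc_cutoff": core.pcc_cutoff,
        },
        outdir / "core_module.json",
    )
    (outdir / "core_genes.txt").write_text("\n".join(core.members) + "\n")
    logger.info("core module: %d genes at |r| >= %.2f", len(core.members), core.pcc_cutoff)
    return core


@_stage("prognosis")
def _prognosis(core, matrix, metadata, config, outdir):
    projection = coremod.pca_project(
        matrix.loc[core.members], var_threshold=config.var_threshold
    )
    projection.scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
    silhouette = coremod.separation_score(projection, metadata["phenotype"])
    k = min(config.k_clusters, len(projection.scores))
    labels = prognosis.cluster_patients(
        projection, k=k, n_components=config.n_components, seed=config.seed
    )
    records = pd.DataFrame(
        {
            "time": metadata["followup_years"],
            "event": metadata["event"].astype(bool),
            "group": labels.reindex(metadata.index).map(lambda c: f"cluster{c}"),
        }
    )
    out = {
        "variance_ratio": [float(v) for v in projection.variance_ratio],
        "pc1_variance_pct": float(projection.variance_ratio[0] * 100.0),
        "n_retained_components": projection.n_retained,
        "phenotype_silhouette": silhouette,
        "cluster_sizes": labels.value_counts().sort_index().to_dict(),
    }
    if records["event"].any() and labels.nunique() >= 2:
        chi2, p = prognosis.log_rank_test(records)
        out["logrank_chi2"], out["logrank_p"] = chi2, p
        cox, extreme = prognosis.extreme_cluster_hr(records, labels)
        out["extreme_cluster_hr"] = {
            "beta": cox.beta,
            "hr": cox.hr,
            "ci": [cox.ci_low, cox.ci_high],
            "p": cox.p,
            "flagged": cox.flagged,
        }
        for label, grp in records.groupby("group"):
            prognosis.kaplan_meier(grp).to_csv(
                outdir / f"km_{label}.tsv", sep="\t", index=False
            )
    else:
        logger.warning("no events or single cluster; survival tests skipped")
    io.write_json(out, outdir / "prognosis.json")
    return out


@_stage("enrich")
def _enrichment(core, deg_genes, matrix, gmt_path, config, outdir):
    collection = enrich.read_gmt(gmt_path)
    background = set(matrix.index)
    results = {}
    for name, query in (
        ("deg", set(deg_genes)),
        ("core_module", set(core.members)),
    ):
        if not query:
            continue
        table = enrich.overrepresentation(
            query, background, collection, alpha=config.enrich_alpha
        )
        table.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
        results[name] = int(table["significant"].sum()) if len(table) else 0
    return results
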