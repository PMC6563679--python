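"""Readers and writers for the pipeline's tabular and graph artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .moddetect import GeneModule

__all__ = [
    "read_expression",
    "write_expression",
    "read_metadata",
    "write_metadata",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "read_graphml",
    "write_modules",
    "read_modules",
    "write_json",
    "read_json",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Gene x sample matrix from TSV/CSV (first column = gene ids)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    matrix = pd.read_csv(path, sep=sep, index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene"
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression intensities must be non-negative")
    return matrix


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    meta.index.name = "sample_id"
    if "phenotype" not in meta.columns or meta["phenotype"].isna().any():
        raise ValueError("metadata must provide a phenotype for every sample")
    if "event" in meta.columns:
        meta["event"] = meta["event"].astype(bool)
    if "followup_years" in meta.columns and (meta["followup_years"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    return meta


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t")


def write_edge_list(edges: pd.DataFrame, path: str | Path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def write_modules(modules: list[GeneModule], tsv_path: str | Path) -> None:
    """Flat member table (module_id, gene, seed_flag) plus a JSON sidecar with
    per-module statistics."""
    rows = []
    for mod in modules:
        for gene in sorted(mod.members):
            rows.append(
                {"module_id": mod.module_id, "gene": gene, "seed_flag": gene == mod.seed}
            )
    pd.DataFrame(rows, columns=["module_id", "gene", "seed_flag"]).to_csv(
        tsv_path, sep="\t", index=False
    )
    stats = {
        mod.module_id: {
            "seed": mod.seed,
            "score": mod.score,
            "n_nodes": mod.n_nodes,
            "avg_connectivity": mod.avg_connectivity,
            "clustering_coefficient": mod.clustering_coefficient,
            "members": sorted(mod.members),
        }
        for mod in modules
    }
    Path(str(tsv_path) + ".json").write_text(json.dumps(stats, indent=2))


def read_modules(tsv_path: str | Path) -> list[GeneModule]:
    stats = json.loads(Path(str(tsv_path) + ".json").read_text())
    modules = []
    for module_id, entry in stats.items():
        mod = GeneModule(
            members=frozenset(entry["members"]),
            seed=entry["seed"],
            score=entry["score"],
            module_id=module_id,
        )
        mod.avg_connectivity = entry["avg_connectivity"]
        mod.clustering_coefficient = entry["clustering_coefficient"]
        modules.append(mod)
    return modules


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if hasattr(obj, "item"):
        return obj.item()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
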