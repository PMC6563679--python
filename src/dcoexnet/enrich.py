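"""Gene-set over-representation analysis against local GMT collections.

Each set is tested with the one-sided hypergeometric upper tail (Fisher's
exact test for enrichment): given a background of N genes, a set of K, and a
query of n genes with k in the set, p = P(X >= k) for X hypergeometric.
P-values are Benjamini-Hochberg adjusted across the tested sets and flagged
significant at adjusted p < 0.01.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy import stats

from .preprocess import benjamini_hochberg

__all__ = ["read_gmt", "write_gmt", "overrepresentation"]


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Parse a GMT file into ``{name: {"description": ..., "genes": set}}``.

    Duplicate member ids within a set are deduplicated; a line with fewer
    than 3 tab-separated fields is rejected with its line number.
    """
    collection: dict[str, dict] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line {lineno}: fewer than 3 fields")
        name, description, *members = fields
        members = {m for m in members if m}
        if not members:
            raise ValueError(f"malformed GMT line {lineno}: empty member list")
        if name in collection:
            raise ValueError(f"duplicate set name {name!r} at line {lineno}")
        collection[name] = {"description": description, "genes": members}
    return collection


def write_gmt(collection: dict[str, dict], path: str | Path) -> None:
    lines = [
        "\t".join([name, entry["description"], *sorted(entry["genes"])])
        for name, entry in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def overrepresentation(
    query: set[str],
    background: set[str],
    collection: dict[str, dict],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within each gene set.

    Set members are intersected with the background before testing. Returns
    one row per set with overlap counts, the upper-tail p, BH-adjusted p, and
    the significance flag at ``adj_p < alpha``.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n_bg, n_query = len(background), len(query)
    rows = []
    for name, entry in collection.items():
        members = entry["genes"] & background
        overlap = len(members & query)
        # P(X >= overlap), X ~ Hypergeom(N=n_bg, K=len(members), n=n_query)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_query))
        rows.append(
            {
                "set": name,
                "description": entry["description"],
                "overlap": overlap,
                "set_size": len(members),
                "query_size": n_query,
                "background_size": n_bg,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        return result.reindex(columns=[*result.columns, "adj_p", "significant"])
    result["adj_p"] = benjamini_hochberg(result["p"].to_numpy())
    result["significant"] = result["adj_p"] < alpha
    return result.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
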