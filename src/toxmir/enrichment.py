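"""Target-set filtering and gene-set overrepresentation analysis.

Predicted miRNA->gene interactions are kept only when supported by at
least 2 of the 7 prediction algorithms (the consensus-intersection
criterion); the union of the filtered targets of a DEM list is then
tested for overrepresentation in each gene set with the one-sided
hypergeometric (Fisher's exact) tail, and p-values are adjusted with the
Benjamini-Hochberg step-up procedure (Holm step-down available).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def filter_targets(
    target_map: pd.DataFrame, min_support: int = 2, n_algorithms: int | None = None
) -> dict[str, set[str]]:
    """miRNA -> set of genes supported by >= min_support algorithms."""
    if n_algorithms is None:
        n_algorithms = int(target_map.attrs.get("n_algorithms", target_map["support"].max()))
    if min_support > n_algorithms:
        raise ValueError(
            f"min_support={min_support} exceeds n_algorithms={n_algorithms}"
        )
    kept = target_map[target_map["support"] >= min_support]
    out: dict[str, set[str]] = {m: set() for m in target_map["mirna_id"].unique()}
    for mid, sub in kept.groupby("mirna_id"):
        out[mid] = set(sub["gene_id"])
    return out


def query_gene_set(
    dem_ids: Iterable[str], filtered_targets: Mapping[str, Iterable[str]]
) -> set[str]:
    """Union of filtered target genes over a DEM list (missing ids contribute nothing)."""
    genes: set[str] = set()
    for mid in dem_ids:
        genes |= set(filtered_targets.get(mid, ()))
    return genes


def fisher_enrichment(
    query: Iterable[str], pathway: Iterable[str], universe: Iterable[str]
) -> float:
    """One-sided overrepresentation p-value, P(X >= k) hypergeometric.

    N = |universe|, K = |pathway ∩ universe|, n = |query|,
    k = |query ∩ pathway|.
    """
    query, pathway, universe = set(query), set(pathway), set(universe)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:10]}")
    N = len(universe)
    K = len(pathway & universe)
    n = len(query)
    k = len(query & pathway)
    if N == 0:
        raise ValueError("empty universe")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float], method: str = "bh") -> list[float]:
    """Multiple-testing adjustment; 'bh' step-up (default) or 'holm' step-down."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"bh": "fdr_bh", "holm": "holm"}.get(method)
    if sm_method is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    _, adj, _, _ = multipletests(p, alpha=0.05, method=sm_method)
    return [float(q) for q in adj]


def enrich(
    query: set[str],
    collection: Mapping[str, Iterable[str]],
    universe: set[str],
    alpha: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Overrepresentation of one query set against every set in a collection."""
    if not collection:
        raise ValueError("empty gene-set collection")
    rows = []
    for set_id in collection:
        pathway = set(collection[set_id]) & universe
        k = len(query & pathway)
        rows.append(
            {
                "set_id": set_id,
                "k": k,
                "n": len(query),
                "K": len(pathway),
                "N": len(universe),
                "p_value": fisher_enrichment(query, pathway, universe),
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = bh_adjust(df["p_value"].tolist(), method=method)
    df["significant"] = df["p_adjusted"] < alpha
    return df.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)


def enrich_all(
    dem_sets_per_condition: Mapping[tuple[str, int], Iterable[str]],
    filtered_targets: Mapping[str, Iterable[str]],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Per-condition enrichment records, sorted by p within condition.

    The default universe is every gene appearing in the filtered target
    map; pass e.g. the collection union to change the policy.
    """
    if universe is None:
        universe = set().union(*[set(g) for g in filtered_targets.values()] or [set()])
    else:
        universe = set(universe)
    frames = []
    for cond, dem_ids in dem_sets_per_condition.items():
        query = query_gene_set(dem_ids, filtered_targets) & universe
        df = enrich(query, collection, universe, alpha=alpha, method=method)
        df.insert(0, "dose_level", cond[0])
        df.insert(1, "timepoint_days", int(cond[1]))
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "dose_level", "timepoint_days", "set_id", "k", "n", "K", "N",
                "p_value", "p_adjusted", "significant",
            ]
        )
    return pd.concat(frames, ignore_index=True)
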