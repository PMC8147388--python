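"""Local over-representation analysis of network clusters.

One-sided hypergeometric tests of a query gene list against a gene-set
collection over a declared universe (all accessions on the filtered
array), with Benjamini-Hochberg adjustment across all tested sets.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .conet import ClusterAssignment
from .core import LnctoxError
from .data_io import GeneSet
from .diffexpr import bh_adjust

ENRICHMENT_COLUMNS = (
    "set_id",
    "set_name",
    "overlap",
    "set_size",
    "query_size",
    "universe_size",
    "p",
    "q",
)


def hypergeom_enrich(
    query: set[str], sets: list[GeneSet], universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a query list.

    Each set is intersected with the universe before testing;
    p = P[X >= overlap] for X ~ Hypergeometric(universe_size, set_size,
    query_size). Results are BH-adjusted across all tested sets and
    sorted by q then p.
    """
    if not query:
        raise LnctoxError("empty query")
    if not universe:
        raise LnctoxError("empty universe")
    stray = query - universe
    if stray:
        raise LnctoxError(f"query member {sorted(stray)[0]!r} not in universe")
    N = len(universe)
    K = len(query)
    rows = []
    for s in sets:
        members = set(s.members) & universe
        if not members:
            continue
        k = len(query & members)
        n = len(members)
        p = float(stats.hypergeom.sf(k - 1, N, n, K))
        rows.append(
            {
                "set_id": s.set_id,
                "set_name": s.set_name,
                "overlap": k,
                "set_size": n,
                "query_size": K,
                "universe_size": N,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows, columns=list(ENRICHMENT_COLUMNS[:-1]))
    if out.empty:
        out["q"] = []
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "p", "set_id"], kind="stable").reset_index(drop=True)


def enrich_clusters(
    mrna_clusters: ClusterAssignment,
    sets: list[GeneSet],
    universe: set[str],
    accession_of: pd.Series | None = None,
    max_q: float = 0.05,
) -> dict[int, pd.DataFrame]:
    """One enrichment run per mRNA cluster; rows with q <= max_q flagged.

    ``accession_of`` maps probe ids to accessions when cluster members
    are probes rather than accessions.
    """
    results: dict[int, pd.DataFrame] = {}
    for cid in sorted(mrna_clusters.labels.unique()):
        members = mrna_clusters.members(int(cid))
        if accession_of is not None:
            members = [accession_of[m] for m in members if m in accession_of.index]
        query = set(members) & universe
        if not query:
            raise LnctoxError(f"mRNA cluster {cid} is empty (or outside the universe)")
        res = hypergeom_enrich(query, sets, universe)
        res["significant"] = res["q"] <= max_q
        results[int(cid)] = res
    return results
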