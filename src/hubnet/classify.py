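"""Top-decile hub / bottleneck / hub-bottleneck classification.

Hubs are the top fraction (default 10%, ceiling-rounded) of *query* genes in
the main component by degree; bottlenecks the top fraction by betweenness;
hub-bottlenecks their intersection; crucial genes their union.  The decile
is computed over the query genes only -- neighbor nodes added to connect the
network are never classified -- and ties are broken by the secondary
centrality and then node id, so the classification is a pure function of its
inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class NodeClassification:
    node_id: str
    is_hub: bool
    is_bottleneck: bool
    is_hub_bottleneck: bool
    rank_by_K: int
    rank_by_BC: int


@dataclass
class CrucialGeneReport:
    classifications: list[NodeClassification]
    hubs: list[str]
    bottlenecks: list[str]
    hub_bottlenecks: list[str]
    crucial_genes: list[str]
    k_top: int


def _query_rows(table: pd.DataFrame, query_ids) -> pd.DataFrame:
    query_ids = set(query_ids)
    if not query_ids:
        raise ValueError("query gene set is empty")
    rows = table[table["node_id"].isin(query_ids)]
    if rows.empty:
        raise ValueError("no query genes present in the centrality table")
    return rows


def k_top_count(n_query: int, fraction: float) -> int:
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    return math.ceil(fraction * n_query)


def select_hubs(table: pd.DataFrame, query_ids, fraction: float = 0.10) -> list[str]:
    """Top-decile query genes by degree (ties: BC desc, then node id asc)."""
    rows = _query_rows(table, query_ids)
    k_top = k_top_count(len(rows), fraction)
    ordered = rows.sort_values(["K", "BC", "node_id"], ascending=[False, False, True], kind="mergesort")
    return ordered["node_id"].head(k_top).tolist()


def select_bottlenecks(table: pd.DataFrame, query_ids, fraction: float = 0.10) -> list[str]:
    """Top-decile query genes by betweenness (ties: K desc, then node id asc)."""
    rows = _query_rows(table, query_ids)
    k_top = k_top_count(len(rows), fraction)
    ordered = rows.sort_values(["BC", "K", "node_id"], ascending=[False, False, True], kind="mergesort")
    return ordered["node_id"].head(k_top).tolist()


def classify_nodes(hubs, bottlenecks, table: pd.DataFrame | None = None) -> CrucialGeneReport:
    """Combine hub and bottleneck calls into the crucial-gene report.

    Crucial genes are the union, hub-bottlenecks the intersection.  When a
    centrality table is given, per-gene ranks by K and BC (dense, within the
    classified set) are attached.
    """
    hubs = list(hubs)
    bottlenecks = list(bottlenecks)
    hub_set, bottle_set = set(hubs), set(bottlenecks)
    crucial = sorted(hub_set | bottle_set)
    hub_bottlenecks = sorted(hub_set & bottle_set)

    if table is not None:
        sub = table[table["node_id"].isin(crucial)]
        rank_k = {g: r for r, g in enumerate(
            sub.sort_values(["K", "BC", "node_id"], ascending=[False, False, True])["node_id"], start=1)}
        rank_bc = {g: r for r, g in enumerate(
            sub.sort_values(["BC", "K", "node_id"], ascending=[False, False, True])["node_id"], start=1)}
    else:
        rank_k = {g: i for i, g in enumerate(hubs, start=1)}
        rank_bc = {g: i for i, g in enumerate(bottlenecks, start=1)}

    classifications = [
        NodeClassification(
            node_id=g,
            is_hub=g in hub_set,
            is_bottleneck=g in bottle_set,
            is_hub_bottleneck=g in hub_set and g in bottle_set,
            rank_by_K=rank_k.get(g, 0),
            rank_by_BC=rank_bc.get(g, 0),
        )
        for g in crucial
    ]
    logger.info("%d hubs, %d bottlenecks, %d hub-bottlenecks, %d crucial genes",
                len(hubs), len(bottlenecks), len(hub_bottlenecks), len(crucial))
    return CrucialGeneReport(
        classifications=classifications,
        hubs=hubs,
        bottlenecks=bottlenecks,
        hub_bottlenecks=hub_bottlenecks,
        crucial_genes=crucial,
        k_top=max(len(hubs), len(bottlenecks)),
    )


def write_classification(report: CrucialGeneReport, table: pd.DataFrame, path) -> None:
    kb = table.set_index("node_id")
    with open(path, "w") as fh:
        fh.write("node_id\tK\tBC\tis_hub\tis_bottleneck\tis_hub_bottleneck\n")
        for c in report.classifications:
            k = int(kb.loc[c.node_id, "K"]) if c.node_id in kb.index else ""
            bc = f"{kb.loc[c.node_id, 'BC']:.6g}" if c.node_id in kb.index else ""
            fh.write(f"{c.node_id}\t{k}\t{bc}\t{c.is_hub}\t{c.is_bottleneck}\t{c.is_hub_bottleneck}\n")
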