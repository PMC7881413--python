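"""Interaction-network construction around a query gene set.

Reads a STRING protein.links-dialect edge list (node, node, combined_score in
[0, 1000]), induces the query subgraph, augments it with the top-m first
neighbors, extracts the main connected component, and runs a power-law
diagnostic on the degree distribution.

The database keeps a node *universe* (every identifier seen in the file)
separately from the thresholded edge graph, so a query gene whose only
interactions fall below the confidence cutoff counts as recognized by the
database but isolated -- the situation that removes seed genes from the main
component.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

QUERY = "query"
NEIGHBOR = "neighbor"


@dataclass
class InteractionDatabase:
    """Undirected confidence-weighted interaction edge set over a node universe."""

    graph: nx.Graph  # edges surviving the score threshold, attr "score"
    universe: set[str]  # every node id seen in the source file
    score_threshold: int = 400


@dataclass
class InteractionNetwork:
    """Query/neighbor-tagged undirected interaction graph with provenance counts."""

    graph: nx.Graph  # node attr "role" in {query, neighbor}; edge attr "score"
    provenance: dict = field(default_factory=dict)

    @property
    def query_nodes(self) -> list[str]:
        return sorted(n for n, r in self.graph.nodes(data="role") if r == QUERY)

    @property
    def neighbor_nodes(self) -> list[str]:
        return sorted(n for n, r in self.graph.nodes(data="role") if r == NEIGHBOR)


@dataclass
class ScaleFreeDiagnostic:
    slope: float | None
    r_squared: float | None
    isolated_fraction: float
    verdict: str
    note: str = ""


def database_from_rows(rows, score_threshold: int = 400) -> InteractionDatabase:
    """Build a database from (node1, node2, score) rows.

    Duplicate unordered pairs keep the maximum score; self-loops are dropped;
    edges below ``score_threshold`` are excluded from the graph but their
    endpoints still join the universe.
    """
    g = nx.Graph()
    universe: set[str] = set()
    for a, b, score in rows:
        if not (0 <= score <= 1000):
            raise ValueError(f"score {score} outside [0, 1000] on edge ({a}, {b})")
        universe.update((a, b))
        if a == b:
            logger.warning("self-loop on %s dropped", a)
            continue
        if score < score_threshold:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    return InteractionDatabase(graph=g, universe=universe, score_threshold=score_threshold)


def load_database(path, score_threshold: int = 400) -> InteractionDatabase:
    """Load a 3-column (node1, node2, combined_score) edge list.

    Whitespace- or tab-separated; a header line is tolerated.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            a, b, raw_score = parts
            try:
                score = int(raw_score)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise ValueError(f"{path}:{lineno}: non-integer score {raw_score!r}") from None
            if not (0 <= score <= 1000):
                raise ValueError(f"{path}:{lineno}: score {score} outside [0, 1000]")
            rows.append((a, b, score))
    if not rows:
        logger.warning("%s: empty interaction database", path)
    return database_from_rows(rows, score_threshold=score_threshold)


def induce_query_network(db: InteractionDatabase, query) -> InteractionNetwork:
    """Subgraph on the query genes recognized by the database.

    Recognized query genes become nodes tagged role="query" (isolated ones
    included); database edges among them are materialized.  Genes absent from
    the database universe are reported as unrecognized.
    """
    query = set(query)
    if not query:
        raise ValueError("query gene set is empty")
    mapped = sorted(query & db.universe)
    unrecognized = sorted(query - db.universe)
    g = nx.Graph()
    g.add_nodes_from(mapped, role=QUERY)
    for a, b, score in db.graph.subgraph(mapped).edges(data="score"):
        g.add_edge(a, b, score=score)
    pct = 100.0 * len(mapped) / len(query)
    logger.info("%d/%d (%.1f%%) query genes recognized by the interaction database",
                len(mapped), len(query), pct)
    prov = {
        "n_query_input": len(query),
        "n_query_mapped": len(mapped),
        "unrecognized": unrecognized,
        "n_neighbors_added": 0,
    }
    return InteractionNetwork(graph=g, provenance=prov)


def add_first_neighbors(db: InteractionDatabase, net: InteractionNetwork, m: int = 20) -> InteractionNetwork:
    """Add the top-m first neighbors of the query set and materialize all db edges.

    Candidates are database nodes adjacent to at least one query node
    (excluding query nodes themselves), ranked by number of distinct query
    connections (desc), then summed confidence of query-incident edges (desc),
    then node id (asc).
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    query = set(net.query_nodes)
    candidates: dict[str, tuple[int, int]] = {}
    for q in query:
        if q not in db.graph:
            continue
        for nbr in db.graph.neighbors(q):
            if nbr in query:
                continue
            n_conn, total = candidates.get(nbr, (0, 0))
            candidates[nbr] = (n_conn + 1, total + db.graph[q][nbr]["score"])
    ranked = sorted(candidates, key=lambda v: (-candidates[v][0], -candidates[v][1], v))
    if len(ranked) < m:
        logger.warning("only %d first-neighbor candidates available (requested %d)", len(ranked), m)
    chosen = ranked[:m]

    g = net.graph.copy()
    g.add_nodes_from(chosen, role=NEIGHBOR)
    enlarged = set(g.nodes)
    for a, b, score in db.graph.subgraph(enlarged).edges(data="score"):
        g.add_edge(a, b, score=score)
    prov = dict(net.provenance)
    prov["n_neighbors_added"] = len(chosen)
    return InteractionNetwork(graph=g, provenance=prov)


def main_component(net: InteractionNetwork) -> tuple[InteractionNetwork, list[str]]:
    """Largest connected component (ties: component containing the smallest node id).

    Returns the component as a new network plus the sorted list of excluded
    nodes; provenance records the isolated-query count and component size.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    components = sorted(nx.connected_components(net.graph), key=lambda c: (-len(c), min(c)))
    keep = components[0]
    excluded = sorted(set(net.graph.nodes) - keep)
    g = net.graph.subgraph(keep).copy()
    prov = dict(net.provenance)
    prov["n_main_component"] = g.number_of_nodes()
    prov["n_query_isolated_removed"] = sum(
        1 for n in excluded if net.graph.nodes[n].get("role") == QUERY
    )
    prov["excluded_nodes"] = excluded
    out = InteractionNetwork(graph=g, provenance=prov)
    logger.info("main component: %d nodes (%d query, %d neighbor); %d nodes excluded",
                g.number_of_nodes(), len(out.query_nodes), len(out.neighbor_nodes), len(excluded))
    return out, excluded


def scale_free_check(net: InteractionNetwork) -> ScaleFreeDiagnostic:
    """Power-law diagnostic on the degree distribution.

    Least-squares fit of log10 P(k) against log10 k over observed degrees
    k >= 1 (histogram normalized over all nodes).  The verdict is
    "scale-free-like" iff slope in [-3, -1], r^2 >= 0.7 and the isolated
    fraction <= 0.1; otherwise "not scale-free", with isolated fraction > 0.3
    flagged as weak interactions between the included genes.
    """
    degrees = np.array([d for _, d in net.graph.degree()], dtype=float)
    n = len(degrees)
    if n == 0:
        raise ValueError("empty network")
    isolated_fraction = float((degrees == 0).mean())
    note = "weak interactions" if isolated_fraction > 0.3 else ""

    if (degrees >= 1).sum() == 0:
        return ScaleFreeDiagnostic(None, None, isolated_fraction, "not scale-free",
                                   note or "all nodes isolated")
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if n < 10 or len(ks) < 3:
        return ScaleFreeDiagnostic(None, None, isolated_fraction, "not scale-free",
                                   note or "too few nodes or degree classes for regression")
    pk = counts / n
    fit = stats.linregress(np.log10(ks), np.log10(pk))
    slope = float(fit.slope)
    r2 = float(fit.rvalue ** 2)
    ok = (-3.0 <= slope <= -1.0) and r2 >= 0.7 and isolated_fraction <= 0.1
    return ScaleFreeDiagnostic(slope, r2, isolated_fraction,
                               "scale-free-like" if ok else "not scale-free", note)


def write_sif(net: InteractionNetwork, path) -> None:
    """Write edges in simple-interaction format: nodeA<TAB>pp<TAB>nodeB."""
    with open(path, "w") as fh:
        for a, b in sorted(map(lambda e: tuple(sorted(e)), net.graph.edges())):
            fh.write(f"{a}\tpp\t{b}\n")


def write_graphml(net: InteractionNetwork, path, centrality=None) -> None:
    """Write GraphML with role (and optional degree/betweenness) node attributes."""
    g = net.graph.copy()
    if centrality is not None:
        for row in centrality.itertuples():
            if row.node_id in g:
                g.nodes[row.node_id]["degree"] = int(row.K)
                g.nodes[row.node_id]["betweenness"] = float(row.BC)
    nx.write_graphml(g, path)
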