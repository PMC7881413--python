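"""Exact degree and betweenness centrality on the main connected component.

Betweenness is computed with Brandes' dependency-accumulation algorithm on
the unweighted, undirected graph (hop-count shortest paths; confidence
scores are deliberately ignored, the default of the common interactive
network-analysis tools).  Raw betweenness B(v) = sum over unordered pairs s != t (both
distinct from v) of sigma_st(v)/sigma_st, normalized to
BC(v) = 2 B(v) / ((n-1)(n-2)) so that 0 <= BC <= 1 on a component of n
nodes; for n < 3 every BC is 0.
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import pandas as pd

from hubnet.network import InteractionNetwork


def degree(net: InteractionNetwork) -> dict[str, int]:
    """Number of distinct neighbors of every node."""
    return {n: int(d) for n, d in net.graph.degree()}


def betweenness(net: InteractionNetwork) -> dict[str, float]:
    """Normalized betweenness centrality via Brandes' algorithm.

    Single-source shortest-path counts by BFS, then back-propagation of pair
    dependencies delta(v) = sum over successors w of
    (sigma_v/sigma_w)(1 + delta(w)).  Each unordered pair is visited from
    both endpoints, so the accumulated total is halved.
    """
    g = net.graph
    n = g.number_of_nodes()
    raw = dict.fromkeys(g, 0.0)
    if n < 3:
        return raw

    for s in g:
        # BFS from s: sigma = shortest-path counts, preds = shortest-path DAG
        sigma = dict.fromkeys(g, 0.0)
        sigma[s] = 1.0
        dist = {s: 0}
        preds: dict = {v: [] for v in g}
        order = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in g.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = dict.fromkeys(g, 0.0)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                raw[w] += delta[w]

    scale = 1.0 / ((n - 1) * (n - 2))  # includes the 1/2 for undirected double counting
    return {v: raw[v] * scale for v in g}


def centrality_table(net: InteractionNetwork) -> pd.DataFrame:
    """Per-node table of role, degree K and normalized betweenness BC.

    The network must be a single connected component (main-component
    extraction guarantees this upstream).  Rows are ordered by node id.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if not nx.is_connected(net.graph):
        raise ValueError("centrality is defined on a connected component; extract it first")
    k = degree(net)
    bc = betweenness(net)
    rows = [
        {"node_id": v, "role": net.graph.nodes[v].get("role", "query"), "K": k[v], "BC": bc[v]}
        for v in sorted(net.graph.nodes)
    ]
    return pd.DataFrame(rows, columns=["node_id", "role", "K", "BC"])


def write_centrality(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["BC_3dp"] = out["BC"].round(3)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
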