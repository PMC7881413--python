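import networkx as nx
import pandas as pd
import pytest

from hubnet.expression_io import ExpressionMatrix, SampleGroups
from hubnet.network import InteractionNetwork


def as_network(graph: nx.Graph, role: str = "query") -> InteractionNetwork:
    """Wrap a plain graph as an InteractionNetwork with a uniform role."""
    g = graph.copy()
    for n in g.nodes:
        g.nodes[n].setdefault("role", role)
    return InteractionNetwork(graph=g)


def random_connected_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos-Renyi graph re-sampled until connected (bounded retries)."""
    for attempt in range(100):
        g = nx.gnp_random_graph(n, p, seed=seed * 100 + attempt)
        if n == 1 or nx.is_connected(g):
            return nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g})
    raise RuntimeError("could not sample a connected graph")


@pytest.fixture
def small_matrix():
    df = pd.DataFrame(
        {
            "S1": [1.0, 5.0, 9.0],
            "S2": [2.0, 6.0, 10.0],
            "S3": [3.0, 7.0, 11.0],
            "S4": [4.0, 8.0, 12.0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    return ExpressionMatrix(values=df, log2_transformed=True)


@pytest.fixture
def two_groups():
    return SampleGroups(mapping={"S1": "case", "S2": "case", "S3": "control", "S4": "control"})
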