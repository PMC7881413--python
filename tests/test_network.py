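import networkx as nx
import pytest

from conftest import as_network
from hubnet.network import (
    add_first_neighbors,
    database_from_rows,
    induce_query_network,
    load_database,
    main_component,
    scale_free_check,
    write_sif,
)


def write_db(path, rows, header=True):
    with open(path, "w") as fh:
        if header:
            fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in rows:
            fh.write(f"{a}\t{b}\t{s}\n")
    return path


def test_load_dedups_keeping_max_score(tmp_path):
    db = load_database(write_db(tmp_path / "db.tsv", [("A", "B", 900), ("B", "A", 700)]),
                       score_threshold=400)
    assert db.graph.number_of_edges() == 1
    assert db.graph["A"]["B"]["score"] == 900


def test_threshold_drops_edge_but_keeps_universe(tmp_path):
    db = load_database(write_db(tmp_path / "db.tsv", [("A", "B", 399), ("C", "D", 400)]),
                       score_threshold=400)
    assert not db.graph.has_edge("A", "B")
    assert db.graph.has_edge("C", "D")
    assert db.universe == {"A", "B", "C", "D"}  # sub-threshold nodes stay recognized


def test_empty_file_gives_empty_database(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    db = load_database(p)
    assert db.graph.number_of_nodes() == 0 and db.universe == set()


@pytest.mark.parametrize("line,err", [
    ("A\tB", "expected 3 columns"),
    ("A\tB\t1500", "outside"),
    ("A\tB\txyz", "non-integer"),
])
def test_malformed_rows_are_hard_errors(tmp_path, line, err):
    p = tmp_path / "bad.tsv"
    p.write_text("A\tC\t500\n" + line + "\n")
    with pytest.raises(ValueError, match=err):
        load_database(p)


def test_induce_reports_unrecognized_and_keeps_isolated():
    db = database_from_rows([("A", "B", 500)], score_threshold=400)
    net = induce_query_network(db, {"A", "B", "C"})
    assert set(net.graph.nodes) == {"A", "B"}
    assert net.graph.number_of_edges() == 1
    assert net.provenance["unrecognized"] == ["C"]
    assert net.provenance["n_query_mapped"] == 2


def test_induce_disjoint_query():
    db = database_from_rows([("A", "B", 500)])
    net = induce_query_network(db, {"X", "Y"})
    assert net.graph.number_of_nodes() == 0
    assert net.provenance["unrecognized"] == ["X", "Y"]


def test_neighbor_ranking_and_tiebreak():
    # X adjacent to 3 query nodes, Y to 1 -> X wins at m=1
    db = database_from_rows([("q1", "X", 500), ("q2", "X", 500), ("q3", "X", 500),
                             ("q1", "Y", 900)])
    net = induce_query_network(db, {"q1", "q2", "q3"})
    out = add_first_neighbors(db, net, m=1)
    assert out.neighbor_nodes == ["X"]
    # m=0 is the identity
    same = add_first_neighbors(db, net, m=0)
    assert set(same.graph.nodes) == set(net.graph.nodes)
    # full tie on connections and summed confidence -> lexicographically smaller id
    db2 = database_from_rows([("q1", "ZB", 500), ("q1", "ZA", 500)])
    out2 = add_first_neighbors(db2, induce_query_network(db2, {"q1"}), m=1)
    assert out2.neighbor_nodes == ["ZA"]


def test_neighbors_materialize_all_database_edges():
    db = database_from_rows([("q1", "X", 500), ("q2", "Y", 500), ("X", "Y", 800)])
    net = add_first_neighbors(db, induce_query_network(db, {"q1", "q2"}), m=2)
    assert net.graph.has_edge("X", "Y")  # neighbor-neighbor edge materialized
    # every added neighbor touches a query node in the database
    for nbr in net.neighbor_nodes:
        assert any(q in db.graph.neighbors(nbr) for q in net.query_nodes)


def test_neighbor_shortfall_adds_all():
    db = database_from_rows([("q1", "X", 500)])
    net = add_first_neighbors(db, induce_query_network(db, {"q1"}), m=5)
    assert net.neighbor_nodes == ["X"]
    assert net.provenance["n_neighbors_added"] == 1


def test_main_component_and_exclusion_report():
    g = nx.Graph()
    nx.add_path(g, ["a", "b", "c", "d", "e"])
    nx.add_path(g, ["x", "y", "z"])
    comp, excluded = main_component(as_network(g))
    assert set(comp.graph.nodes) == {"a", "b", "c", "d", "e"}
    assert excluded == ["x", "y", "z"]
    assert comp.provenance["n_main_component"] == 5
    assert comp.provenance["n_query_isolated_removed"] == 3

    full, excluded2 = main_component(as_network(nx.complete_graph(4)))
    assert excluded2 == []


def test_main_component_tie_goes_to_smallest_node_id():
    g = nx.Graph()
    g.add_edge("b1", "b2")
    g.add_edge("a1", "a2")
    comp, _ = main_component(as_network(g))
    assert set(comp.graph.nodes) == {"a1", "a2"}


def test_main_component_empty_is_error():
    with pytest.raises(ValueError):
        main_component(as_network(nx.Graph()))


def test_counts_invariant_under_row_order_and_renaming(tmp_path):
    rows = [("A", "B", 500), ("B", "C", 600), ("C", "D", 700), ("A", "D", 800)]
    db1 = database_from_rows(rows)
    db2 = database_from_rows(rows[::-1])
    assert nx.utils.graphs_equal(db1.graph, db2.graph)
    renamed = [(a.lower(), b.lower(), s) for a, b, s in rows]
    db3 = database_from_rows(renamed)
    assert db3.graph.number_of_nodes() == db1.graph.number_of_nodes()
    assert db3.graph.number_of_edges() == db1.graph.number_of_edges()


def test_scale_free_check_mechanics():
    # 50 isolated nodes + a triangle: overwhelmingly isolated -> weak interactions
    g = nx.Graph()
    g.add_nodes_from(f"i{i}" for i in range(50))
    g.add_edges_from([("t1", "t2"), ("t2", "t3"), ("t1", "t3")])
    d = scale_free_check(as_network(g))
    assert d.isolated_fraction == pytest.approx(50 / 53)
    assert d.verdict == "not scale-free"
    assert d.note == "weak interactions"
    # star K1,9: no isolates, only two degree classes -> regression refused
    star = scale_free_check(as_network(nx.star_graph(9)))
    assert star.isolated_fraction == 0.0
    assert star.verdict == "not scale-free"


def test_scale_free_check_all_isolated():
    g = nx.Graph()
    g.add_nodes_from(range(12))
    d = scale_free_check(as_network(g))
    assert d.verdict == "not scale-free" and d.slope is None


def test_preferential_attachment_is_scale_free_like():
    wins = 0
    for seed in range(10):
        g = nx.barabasi_albert_graph(500, 2, seed=seed)
        wins += scale_free_check(as_network(g)).verdict == "scale-free-like"
    assert wins >= 8


def test_sif_output(tmp_path):
    g = nx.Graph([("B", "A"), ("B", "C")])
    p = tmp_path / "net.sif"
    write_sif(as_network(g), p)
    assert p.read_text() == "A\tpp\tB\nB\tpp\tC\n"
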