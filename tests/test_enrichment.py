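from itertools import combinations
from math import comb

import numpy as np
import pytest

from hubnet.enrichment import (
    AnnotationCollection,
    cluster_terms,
    hypergeometric_enrich,
    kappa_matrix,
    read_gmt,
    write_gmt,
)


def collection(term_sets: dict, universe=None):
    terms = [(tid, tid, frozenset(genes)) for tid, genes in term_sets.items()]
    if universe is None:
        universe = frozenset().union(*(t[2] for t in terms))
    return AnnotationCollection(terms=terms, universe=frozenset(universe))


def enumeration_p(N, K_term, n_query, k_min):
    """Oracle: exhaustive enumeration of all n_query-subsets of an N-universe."""
    hits = total = 0
    term = set(range(K_term))
    for subset in combinations(range(N), n_query):
        total += 1
        hits += len(term & set(subset)) >= k_min
    return hits / total


def test_hypergeometric_matches_direct_sum():
    # N=20, K_term=5, n_query=4, k=3: C(5,3)C(15,1)+C(5,4)C(15,0) over C(20,4)
    expected = (comb(5, 3) * comb(15, 1) + comb(5, 4)) / comb(20, 4)
    assert expected == pytest.approx(155 / 4845)
    universe = [f"g{i}" for i in range(20)]
    coll = collection({"T": universe[:5]}, universe=universe)
    # degenerate second term keeps the universe at 20 genes
    coll = AnnotationCollection(terms=coll.terms + [("U", "U", frozenset(universe))],
                                universe=frozenset(universe))
    query = universe[:3] + [universe[10]]  # overlap 3 with T
    res = {r.term_id: r for r in hypergeometric_enrich(query, coll, min_overlap=2)}
    assert res["T"].k == 3
    assert res["T"].p_value == pytest.approx(expected, rel=1e-12)
    assert res["T"].p_value == pytest.approx(enumeration_p(20, 5, 4, 3), rel=1e-12)


@pytest.mark.parametrize("N,K_term,n_query,k_min", [
    (12, 4, 5, 2), (15, 6, 4, 3), (18, 9, 3, 1), (25, 5, 4, 2),
])
def test_hypergeometric_matches_enumeration(N, K_term, n_query, k_min):
    universe = [f"g{i}" for i in range(N)]
    coll = collection({"T": universe[:K_term], "ALL": universe}, universe=universe)
    query = universe[: k_min] + universe[K_term: K_term + (n_query - k_min)]
    res = {r.term_id: r for r in hypergeometric_enrich(query, coll, min_overlap=1)}
    assert res["T"].p_value == pytest.approx(enumeration_p(N, K_term, n_query, k_min), rel=1e-10)


def test_term_equal_to_universe_has_p_one():
    universe = [f"g{i}" for i in range(8)]
    coll = collection({"ALL": universe}, universe=universe)
    res = hypergeometric_enrich(universe[:3], coll, min_overlap=1)
    assert res[0].p_value == 1.0


def test_min_overlap_excludes_terms():
    universe = [f"g{i}" for i in range(10)]
    coll = collection({"T1": universe[:4], "T2": universe[4:8]}, universe=universe)
    res = hypergeometric_enrich([universe[0], universe[4], universe[5]], coll, min_overlap=2)
    assert [r.term_id for r in res] == ["T2"]  # T1 overlap 1 < min_overlap


def test_p_monotone_in_overlap():
    universe = [f"g{i}" for i in range(30)]
    ps = []
    for k in (1, 2, 3, 4):
        coll = collection({"T": universe[:8], "ALL": universe}, universe=universe)
        query = universe[:k] + universe[8: 8 + 4 - k]
        res = {r.term_id: r for r in hypergeometric_enrich(query, coll, min_overlap=1)}
        ps.append(res["T"].p_value)
    assert ps == sorted(ps, reverse=True)


def test_bh_preserves_order_and_bounds():
    rng = np.random.default_rng(0)
    universe = [f"g{i}" for i in range(60)]
    sets = {f"T{i}": list(rng.choice(universe, size=8, replace=False)) for i in range(12)}
    coll = collection(sets, universe=universe)
    res = hypergeometric_enrich(universe[:10], coll, min_overlap=1)
    ps = [r.p_value for r in res]
    qs = [r.q_value for r in res]
    assert ps == sorted(ps)
    assert qs == sorted(qs)
    assert all(0 < q <= 1 for q in qs)


def test_empty_universe_is_hard_error():
    coll = AnnotationCollection(terms=[], universe=frozenset())
    with pytest.raises(ValueError):
        hypergeometric_enrich({"g1"}, coll)


def test_kappa_identical_disjoint_and_handworked():
    universe = [f"g{i}" for i in range(1, 7)]
    coll = collection({"A": ["g1", "g2"], "B": ["g2", "g3"],
                       "Acopy": ["g1", "g2"],
                       "H1": ["g1", "g2", "g3"], "H2": ["g4", "g5", "g6"]},
                      universe=universe)
    res = hypergeometric_enrich(["g1", "g2", "g3", "g4"], coll, min_overlap=1)
    km = kappa_matrix(res, coll)
    assert km.loc["A", "Acopy"] == pytest.approx(1.0)
    # halves of the universe in perfect disagreement
    assert km.loc["H1", "H2"] == pytest.approx(-1.0)
    # hand-worked 2x2 for A vs B: a=1,b=1,c=1,d=3 -> po=2/3, pe=5/9, kappa=1/4
    assert km.loc["A", "B"] == pytest.approx(0.25)
    # symmetric with unit diagonal
    assert np.allclose(km.values, km.values.T)
    assert np.allclose(np.diag(km.values), 1.0)


def test_clustering_extremes():
    universe = [f"g{i}" for i in range(12)]
    # three near-identical terms -> one cluster
    close = collection({"T1": universe[:5], "T2": universe[:5], "T3": universe[1:6]},
                       universe=universe)
    res = hypergeometric_enrich(universe[:5], close, min_overlap=1)
    out = cluster_terms(res, close, kappa_threshold=0.4)
    assert len({r.cluster_id for r in out}) == 1
    # three disjoint terms -> three singleton clusters
    far = collection({"T1": universe[:4], "T2": universe[4:8], "T3": universe[8:]},
                     universe=universe)
    res2 = hypergeometric_enrich(universe, far, min_overlap=1)
    for r in res2:
        r.significant = True
    out2 = cluster_terms(res2, far, kappa_threshold=0.4)
    assert len({r.cluster_id for r in out2}) == 3


def test_clustering_invariant_under_term_order():
    universe = [f"g{i}" for i in range(20)]
    sets = {"B1a": universe[:6], "B1b": universe[:6], "B2a": universe[10:16],
            "B2b": universe[10:16]}
    coll = collection(sets, universe=universe)
    query = universe[:6] + universe[10:16]
    res = hypergeometric_enrich(query, coll, min_overlap=1)
    assert any(r.significant for r in res)
    fwd = {r.term_id: r.cluster_id for r in cluster_terms(res, coll)}
    rev = {r.term_id: r.cluster_id for r in cluster_terms(res[::-1], coll)}
    groups_fwd = {frozenset(t for t, c in fwd.items() if c == cid) for cid in set(fwd.values())}
    groups_rev = {frozenset(t for t, c in rev.items() if c == cid) for cid in set(rev.values())}
    assert groups_fwd == groups_rev


def test_gmt_round_trip(tmp_path):
    universe = [f"g{i}" for i in range(9)]
    coll = collection({"T1": universe[:4], "T2": universe[4:]}, universe=universe)
    p = tmp_path / "sets.gmt"
    write_gmt(coll, p)
    again = read_gmt(p)
    assert again.gene_sets() == coll.gene_sets()
    assert again.universe == coll.universe


def test_gmt_background_restricts_universe(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("T1\tdesc\tg1\tg2\tg3\nT2\tdesc\tg3\tg4\n")
    coll = read_gmt(p, background=["g1", "g2", "g3"])
    assert coll.universe == {"g1", "g2", "g3"}
    assert coll.gene_sets()["T2"] == {"g3"}
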