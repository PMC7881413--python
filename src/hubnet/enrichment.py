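"""Over-representation analysis with kappa-score term grouping.

Each annotation term is tested for overlap with the query gene list by the
hypergeometric upper tail P[X >= k], X ~ Hypergeometric(N, K_term, n_query),
with Benjamini-Hochberg adjustment across tested terms.  Significant terms
(p <= 0.05 by default) are then grouped: Cohen's kappa is computed between
every pair of term gene-membership vectors over the universe, terms with
kappa at or above a threshold (default 0.4) are linked, and connected
components of that term graph form the clusters, each labeled by its
smallest-p member.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """Named gene sets plus the gene universe they live in."""

    terms: list[tuple[str, str, frozenset]]  # (term_id, term_name, genes)
    universe: frozenset

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate term ids")
        for term_id, _, genes in self.terms:
            if not genes:
                raise ValueError(f"term {term_id} has an empty gene set")
            if not genes <= self.universe:
                raise ValueError(f"term {term_id} has genes outside the universe")

    def gene_sets(self) -> dict[str, frozenset]:
        return {tid: genes for tid, _, genes in self.terms}


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    overlap_genes: frozenset
    k: int
    K_term: int
    n_query: int
    N: int
    p_value: float
    q_value: float = np.nan
    significant: bool = False
    cluster_id: int | None = None


def read_gmt(path, background=None) -> AnnotationCollection:
    """Read GMT (term_id<TAB>description<TAB>gene...).

    The universe is the union of all term genes, optionally intersected with
    ``background``; term gene sets are restricted to the universe.
    """
    raw = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need term, description and >= 1 gene")
            raw.append((parts[0], parts[1], frozenset(g for g in parts[2:] if g)))
    universe = frozenset().union(*(genes for _, _, genes in raw)) if raw else frozenset()
    if background is not None:
        universe = universe & frozenset(background)
    terms = [(tid, name, genes & universe) for tid, name, genes in raw]
    terms = [(tid, name, genes) for tid, name, genes in terms if genes]
    return AnnotationCollection(terms=terms, universe=universe)


def write_gmt(coll: AnnotationCollection, path) -> None:
    with open(path, "w") as fh:
        for term_id, name, genes in coll.terms:
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def hypergeometric_enrich(query, coll: AnnotationCollection, min_overlap: int = 2,
                          p_cutoff: float = 0.05) -> list[EnrichmentResult]:
    """Hypergeometric upper-tail test per term, BH across tested terms, sorted by p.

    Terms overlapping the query in fewer than ``min_overlap`` genes are not
    tested and are absent from the output.
    """
    if not coll.universe:
        raise ValueError("empty annotation universe")
    query_in_universe = frozenset(query) & coll.universe
    if not query_in_universe:
        raise ValueError("query does not intersect the annotation universe")
    N = len(coll.universe)
    n_query = len(query_in_universe)

    results = []
    for term_id, term_name, genes in coll.terms:
        overlap = genes & query_in_universe
        k = len(overlap)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, len(genes), n_query))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        results.append(EnrichmentResult(
            term_id=term_id, term_name=term_name, overlap_genes=overlap,
            k=k, K_term=len(genes), n_query=n_query, N=N, p_value=p,
        ))
    if not results:
        logger.info("no term reached the minimum overlap of %d", min_overlap)
        return []
    q = multipletests([r.p_value for r in results], method="fdr_bh")[1]
    results = [replace(r, q_value=float(qi), significant=r.p_value <= p_cutoff)
               for r, qi in zip(results, q)]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    logger.info("%d/%d tested terms significant at p<=%g",
                sum(r.significant for r in results), len(results), p_cutoff)
    return results


def kappa_matrix(results: list[EnrichmentResult], coll: AnnotationCollection) -> pd.DataFrame:
    """Cohen's kappa between term gene memberships over the universe.

    kappa = (p_obs - p_exp) / (1 - p_exp) from the 2x2 membership table of
    universe genes; the diagonal is 1, and a degenerate table (p_exp = 1,
    i.e. a term covering the whole universe compared with itself-like
    coverage) yields kappa 0 with a warning.
    """
    if not results:
        raise ValueError("need at least one term")
    genes = sorted(coll.universe)
    N = len(genes)
    sets = coll.gene_sets()
    membership = np.array([[g in sets[r.term_id] for g in genes] for r in results], dtype=float)

    n = len(results)
    kappa = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = float(np.sum(membership[i] * membership[j]))            # in both
            b = float(np.sum(membership[i] * (1 - membership[j])))      # i only
            c = float(np.sum((1 - membership[i]) * membership[j]))      # j only
            d = N - a - b - c                                           # in neither
            p_obs = (a + d) / N
            p_exp = ((a + b) * (a + c) + (c + d) * (b + d)) / (N * N)
            if p_exp == 1.0:
                logger.warning("degenerate membership table for %s vs %s; kappa set to 0",
                               results[i].term_id, results[j].term_id)
                k = 0.0
            else:
                k = (p_obs - p_exp) / (1.0 - p_exp)
            kappa[i, j] = kappa[j, i] = k
    ids = [r.term_id for r in results]
    return pd.DataFrame(kappa, index=ids, columns=ids)


def cluster_terms(results: list[EnrichmentResult], coll: AnnotationCollection,
                  kappa_threshold: float = 0.4) -> list[EnrichmentResult]:
    """Assign cluster ids to significant terms by kappa-graph connected components.

    Terms are linked when kappa >= threshold; each connected component is one
    cluster, labeled (and its id ordered) by the smallest p-value it
    contains.  Non-significant terms keep cluster_id None.
    """
    if not (0 < kappa_threshold < 1):
        raise ValueError("kappa_threshold must be in (0, 1)")
    significant = [r for r in results if r.significant]
    if not significant:
        return list(results)
    km = kappa_matrix(significant, coll)
    g = nx.Graph()
    g.add_nodes_from(km.index)
    ids = list(km.index)
    for i, t1 in enumerate(ids):
        for t2 in ids[i + 1:]:
            if km.loc[t1, t2] >= kappa_threshold:
                g.add_edge(t1, t2)
    best_p = {r.term_id: r.p_value for r in significant}
    components = sorted(nx.connected_components(g),
                        key=lambda c: min((best_p[t], t) for t in c))
    assignment = {t: cid for cid, comp in enumerate(components, start=1) for t in comp}
    out = [replace(r, cluster_id=assignment.get(r.term_id)) for r in results]
    logger.info("%d significant terms grouped into %d clusters", len(significant), len(components))
    return out


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "term_id": r.term_id, "term_name": r.term_name,
            "genes": ",".join(sorted(r.overlap_genes)),
            "k": r.k, "K_term": r.K_term, "n_query": r.n_query, "N": r.N,
            "p_value": r.p_value, "q_value": r.q_value,
            "significant": r.significant, "cluster_id": r.cluster_id,
        }
        for r in results
    ])


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
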