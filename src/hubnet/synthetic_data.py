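"""Synthetic fixtures with planted ground truth for every pipeline stage.

Three generators and one literal fixture:

* ``simulate_expression`` draws a 20 + 20 case/control log2 expression matrix
  with a planted set of differentially expressed genes (|log2FC| above 1, so
  FC > 2 by construction).
* ``simulate_database`` builds a STRING-dialect interaction database around a
  preferential-attachment backbone, wiring a known subset of the query genes
  into it (one designated target gene with maximal degree and betweenness
  among query genes, a block of genes recognized only through sub-threshold
  edges, and a block absent from the database altogether).
* ``simulate_annotations`` writes GMT-style term blocks: terms within a
  block share a gene core (high kappa), blocks are disjoint (low kappa),
  and background terms fill out the gene universe.
* ``paper_fixture`` is the literal seven-row worked example of hub and
  bottleneck centralities used in tests and documentation.

Every generator is a pure function of its config: all randomness flows from
``SimulationConfig.seed`` through per-stage ``numpy`` generators, never
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from hubnet.enrichment import AnnotationCollection
from hubnet.expression_io import ExpressionMatrix, SampleGroups
from hubnet.network import InteractionDatabase, database_from_rows


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 20+20 samples, 81 planted DE genes, 69 of them
    recognized by the database, 39 wired into the connected core, 20 neighbor
    anchors."""

    seed: int = 0
    # expression stage
    n_genes: int = 2000
    n_case: int = 20
    n_control: int = 20
    n_de_genes: int = 81
    log2fc_range: tuple[float, float] = (1.2, 3.0)
    noise_sd: float = 0.25
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    # interaction-database stage
    db_nodes: int = 400
    attachment: int = 2
    score_threshold: int = 400
    n_query_mapped: int = 69
    n_query_connected: int = 39
    n_anchors: int = 20
    target_anchor_links: int = 12
    # annotation stage
    n_blocks: int = 3
    n_terms_per_block: int = 6
    core_size: int = 10
    term_extras: int = 2
    background_term_size: int = 15

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")
        if self.log2fc_range[0] <= 1.0:
            raise ValueError("log2fc_range lower bound must exceed 1 (planted FC > 2)")
        if not (self.n_query_connected <= self.n_query_mapped <= self.n_de_genes):
            raise ValueError("need n_query_connected <= n_query_mapped <= n_de_genes")
        if self.target_anchor_links > self.n_anchors:
            raise ValueError("target_anchor_links exceeds n_anchors")


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_expression(cfg: SimulationConfig) -> tuple[ExpressionMatrix, SampleGroups, pd.DataFrame]:
    """Case/control log2 matrix with planted DE genes.

    Per-gene baseline ~ Normal(baseline_mean, baseline_sd); i.i.d. Normal(0,
    noise_sd) noise; case samples of each planted gene shifted by a signed
    effect with |log2FC| drawn uniformly from ``log2fc_range``.  Returns the
    matrix, the sample grouping, and the planted truth (gene_id, log2fc).
    """
    rng = _rng(cfg, 1)
    width = len(str(cfg.n_genes))
    gene_ids = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    samples = [f"case{i+1:02d}" for i in range(cfg.n_case)] + \
              [f"ctrl{i+1:02d}" for i in range(cfg.n_control)]

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    values = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(samples)))

    de_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_de_genes, replace=False))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_de_genes)
    magnitudes = rng.uniform(*cfg.log2fc_range, size=cfg.n_de_genes)
    effects = signs * magnitudes
    values[de_idx, : cfg.n_case] += effects[:, None]

    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    matrix = ExpressionMatrix(values=df, log2_transformed=True)
    groups = SampleGroups(mapping={
        **{s: "case" for s in samples[: cfg.n_case]},
        **{s: "control" for s in samples[cfg.n_case:]},
    })
    truth = pd.DataFrame({"gene_id": [gene_ids[i] for i in de_idx], "log2fc": effects})
    return matrix, groups, truth


@dataclass
class SimulatedDatabase:
    """Interaction database plus the planted wiring truth."""

    db: InteractionDatabase
    edge_rows: list[tuple[str, str, int]]  # pre-threshold rows, for serialization
    target_gene: str
    connected_genes: list[str] = field(default_factory=list)  # incl. target
    isolated_genes: list[str] = field(default_factory=list)   # mapped, sub-threshold only
    unrecognized_genes: list[str] = field(default_factory=list)
    anchors: list[str] = field(default_factory=list)


def simulate_database(cfg: SimulationConfig, planted_query) -> SimulatedDatabase:
    """Database with a preferential-attachment backbone and planted query wiring.

    The 20 highest-degree backbone nodes act as anchors.  Each ordinary
    connected query gene is attached to two ring-consecutive anchors plus one
    unique non-anchor node; the designated target gene is attached to many
    distinct anchors spread over the ring, giving it strictly maximal degree
    (and, in practice, maximal betweenness) among the query genes.  A further
    block of query genes appears only through sub-threshold edges (recognized
    but isolated), and the remainder is left out of the database entirely.
    """
    rng = _rng(cfg, 2)
    planted_query = sorted(set(planted_query))
    if len(planted_query) < cfg.n_query_mapped:
        raise ValueError("planted query smaller than n_query_mapped")

    backbone = nx.barabasi_albert_graph(cfg.db_nodes, cfg.attachment,
                                        seed=int(rng.integers(2**31 - 1)))
    width = len(str(cfg.db_nodes))
    name = {i: f"P{i:0{width}d}" for i in backbone.nodes}
    by_degree = sorted(backbone.nodes, key=lambda v: (-backbone.degree[v], v))
    anchors = [name[v] for v in by_degree[: cfg.n_anchors]]
    non_anchors = [name[v] for v in by_degree[cfg.n_anchors:]]

    hi = lambda size=None: rng.integers(cfg.score_threshold, 1001, size=size)
    lo = lambda: int(rng.integers(100, cfg.score_threshold))

    rows: list[tuple[str, str, int]] = []
    for a, b in sorted(backbone.edges()):
        rows.append((name[a], name[b], int(hi())))

    chosen = list(rng.choice(planted_query, size=cfg.n_query_mapped, replace=False))
    connected = sorted(chosen[: cfg.n_query_connected])
    isolated = sorted(chosen[cfg.n_query_connected:])
    unrecognized = sorted(set(planted_query) - set(chosen))
    target = connected[int(rng.integers(len(connected)))]
    ordinary = [g for g in connected if g != target]

    # ordinary genes: two ring-consecutive anchors (connected ring) + one unique non-anchor
    partners = list(rng.choice(non_anchors, size=len(ordinary), replace=False))
    for i, gene in enumerate(ordinary):
        rows.append((gene, anchors[i % cfg.n_anchors], int(hi())))
        rows.append((gene, anchors[(i + 1) % cfg.n_anchors], int(hi())))
        rows.append((gene, partners[i], int(hi())))
    # target: many distinct anchors spread over the ring
    target_anchors = [anchors[j] for j in
                      rng.choice(cfg.n_anchors, size=cfg.target_anchor_links, replace=False)]
    for a in target_anchors:
        rows.append((target, a, int(hi())))
    # isolated genes: sub-threshold edges only (recognized by the database, no usable link)
    for gene in isolated:
        partner = non_anchors[int(rng.integers(len(non_anchors)))]
        rows.append((gene, partner, lo()))

    db = database_from_rows(rows, score_threshold=cfg.score_threshold)
    target_deg = db.graph.degree[target]
    other_max = max(db.graph.degree[g] for g in ordinary)
    assert target_deg > other_max, "target gene must dominate query degrees by construction"
    return SimulatedDatabase(db=db, edge_rows=rows, target_gene=target,
                             connected_genes=connected, isolated_genes=isolated,
                             unrecognized_genes=unrecognized, anchors=anchors)


def write_database_tsv(sim: SimulatedDatabase, path) -> None:
    """Write the full pre-threshold edge list (node1, node2, combined_score)."""
    with open(path, "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in sim.edge_rows:
            fh.write(f"{a}\t{b}\t{s}\n")


@dataclass
class PaperFixture:
    """Seven-row worked example of hub/bottleneck centralities on a 39-gene
    query component: four hubs by degree, four bottlenecks by betweenness,
    one gene (GATA3) in both lists."""

    table: pd.DataFrame
    hubs: list[str]
    bottlenecks: list[str]
    n_query: int = 39


def paper_fixture() -> PaperFixture:
    rows = [
        ("GATA3", 28, 0.038),
        ("IL-7", 26, 0.007),
        ("CD28", 26, 0.006),
        ("CD5", 25, 0.005),
        ("TXN", 9, 0.069),
        ("ETS-1", 19, 0.042),
        ("CCR7", 23, 0.036),
    ]
    table = pd.DataFrame(
        [{"node_id": g, "role": "query", "K": k, "BC": bc} for g, k, bc in rows],
        columns=["node_id", "role", "K", "BC"],
    )
    return PaperFixture(
        table=table,
        hubs=["GATA3", "IL-7", "CD28", "CD5"],
        bottlenecks=["TXN", "ETS-1", "GATA3", "CCR7"],
    )


def simulate_annotations(cfg: SimulationConfig, genes, focus_genes=None
                         ) -> tuple[AnnotationCollection, dict[str, int]]:
    """Block-structured annotation collection with planted clusters.

    Genes are split into ``n_blocks`` disjoint pools.  Each block contributes
    ``n_terms_per_block`` terms sharing a ``core_size``-gene core (pairwise
    kappa within a block is high) plus ``term_extras`` pool-private extras;
    cross-block term pairs are disjoint (kappa near zero).  ``focus_genes``
    (e.g. the genes a downstream enrichment will query) are distributed
    round-robin into the block cores so each block's terms overlap them.
    Background terms partition the remaining genes so the universe covers the
    full gene list.  Returns the collection and the planted term -> block map.
    """
    rng = _rng(cfg, 3)
    genes = list(dict.fromkeys(genes))
    focus = list(dict.fromkeys(focus_genes)) if focus_genes else []
    if any(g not in set(genes) for g in focus):
        raise ValueError("focus_genes must be a subset of genes")
    rest = [g for g in genes if g not in set(focus)]
    rng.shuffle(rest)

    need = cfg.n_blocks * (cfg.core_size + cfg.n_terms_per_block * cfg.term_extras)
    if len(genes) < need:
        raise ValueError(f"need at least {need} genes for the block structure")

    # round-robin focus genes, then fill cores and pools from the shuffled rest
    cores: list[list[str]] = [[] for _ in range(cfg.n_blocks)]
    for i, g in enumerate(focus):
        cores[i % cfg.n_blocks].append(g)
    cursor = 0
    pools: list[list[str]] = []
    for b in range(cfg.n_blocks):
        while len(cores[b]) < cfg.core_size:
            cores[b].append(rest[cursor])
            cursor += 1
        n_extra = cfg.n_terms_per_block * cfg.term_extras
        pools.append(rest[cursor: cursor + n_extra])
        cursor += n_extra

    terms: list[tuple[str, str, frozenset]] = []
    planted: dict[str, int] = {}
    for b in range(cfg.n_blocks):
        extra_pool = list(pools[b])
        rng.shuffle(extra_pool)
        for t in range(cfg.n_terms_per_block):
            term_id = f"BLOCK{b+1}_T{t+1}"
            extras = extra_pool[t * cfg.term_extras: (t + 1) * cfg.term_extras]
            terms.append((term_id, f"planted block {b+1} term {t+1}",
                          frozenset(cores[b]) | frozenset(extras)))
            planted[term_id] = b + 1

    leftovers = rest[cursor:]
    for i in range(0, len(leftovers), cfg.background_term_size):
        chunk = leftovers[i: i + cfg.background_term_size]
        if chunk:
            terms.append((f"BG_T{i // cfg.background_term_size + 1}",
                          "background term", frozenset(chunk)))
    coll = AnnotationCollection(terms=terms, universe=frozenset().union(*(t[2] for t in terms)))
    return coll, planted
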