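"""End-to-end orchestration: DEG filtering -> network -> centrality -> classification -> enrichment.

``run_pipeline`` executes every stage on files named in a ``PipelineConfig``,
writes per-stage outputs into the output directory, and returns a run report
echoing the stage counts (significant DEGs, mapped genes, isolated queries
removed, main-component size, hubs/bottlenecks/hub-bottlenecks, significant
terms and clusters).  Identical config and inputs give identical outputs.
A stage failure aborts the run with the stage name and removes any partial
outputs written so far.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from hubnet import centrality, classify, deg, enrichment, expression_io, network

logger = logging.getLogger(__name__)

STAGES = ["load", "deg", "network", "centrality", "classify", "enrichment", "report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    expression: str
    sample_map: str
    database: str
    gmt: str
    outdir: str
    top_n: int = 250
    fc_cutoff: float = 2.0
    p_cutoff: float = 0.05
    score_threshold: int = 400
    n_neighbors: int = 20
    top_fraction: float = 0.10
    kappa_threshold: float = 0.4
    min_overlap: int = 2
    comparability_tol: float = 0.5
    case_label: str = "case"
    control_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if not (0 < self.kappa_threshold < 1):
            raise ValueError("kappa_threshold must be in (0, 1)")
        if self.top_n < 1 or self.n_neighbors < 0 or self.min_overlap < 1:
            raise ValueError("threshold out of documented range")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def run_pipeline(cfg: PipelineConfig) -> dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def out(name: str) -> Path:
        p = outdir / name
        written.append(p)
        return p

    stage = "load"
    try:
        matrix = expression_io.read_expression(cfg.expression)
        groups = expression_io.read_sample_map(cfg.sample_map, cfg.case_label, cfg.control_label)
        groups.validate_against(matrix)
        qc = expression_io.check_comparability(matrix, tol=cfg.comparability_tol)
        logger.info("[load] %d genes x %d samples; comparability %s",
                    *matrix.shape, "pass" if qc.passed else "FAIL")

        stage = "deg"
        table = deg.differential_expression(matrix, groups)
        top = deg.select_top(table, n=cfg.top_n)
        top = deg.flag_significant(top, fc_cutoff=cfg.fc_cutoff, p_cutoff=cfg.p_cutoff)
        top.to_tsv(out("deg.tsv"))
        query = top.significant_genes
        logger.info("[deg] top %d by p-value; %d significant (FC>%g, p<=%g)",
                    len(top), top.n_significant, cfg.fc_cutoff, cfg.p_cutoff)
        if not query:
            raise ValueError("no significant DEGs; nothing to build a network from")

        stage = "network"
        db = network.load_database(cfg.database, score_threshold=cfg.score_threshold)
        net = network.induce_query_network(db, query)
        pre_diag = network.scale_free_check(net)
        net = network.add_first_neighbors(db, net, m=cfg.n_neighbors)
        component, excluded = network.main_component(net)
        post_diag = network.scale_free_check(component)
        network.write_sif(component, out("network.sif"))

        stage = "centrality"
        ctable = centrality.centrality_table(component)
        centrality.write_centrality(ctable, out("centrality.tsv"))
        network.write_graphml(component, out("network.graphml"), centrality=ctable)

        stage = "classify"
        query_in_component = set(component.query_nodes)
        hubs = classify.select_hubs(ctable, query_in_component, fraction=cfg.top_fraction)
        bottlenecks = classify.select_bottlenecks(ctable, query_in_component, fraction=cfg.top_fraction)
        report = classify.classify_nodes(hubs, bottlenecks, table=ctable)
        classify.write_classification(report, ctable, out("classification.tsv"))

        stage = "enrichment"
        coll = enrichment.read_gmt(cfg.gmt)
        results = enrichment.hypergeometric_enrich(report.crucial_genes, coll,
                                                   min_overlap=cfg.min_overlap,
                                                   p_cutoff=cfg.p_cutoff)
        results = enrichment.cluster_terms(results, coll, kappa_threshold=cfg.kappa_threshold)
        enrichment.write_enrichment(results, out("enrichment.tsv"))
        n_clusters = len({r.cluster_id for r in results if r.cluster_id is not None})

        stage = "report"
        run_report = {
            "n_genes": matrix.shape[0],
            "n_samples": matrix.shape[1],
            "comparability_pass": qc.passed,
            "n_top": len(top),
            "n_significant_degs": top.n_significant,
            "n_query_input": net.provenance["n_query_input"],
            "n_query_mapped": net.provenance["n_query_mapped"],
            "unrecognized_genes": net.provenance["unrecognized"],
            "n_neighbors_added": net.provenance["n_neighbors_added"],
            "n_query_isolated_removed": component.provenance["n_query_isolated_removed"],
            "n_main_component": component.provenance["n_main_component"],
            "n_query_in_component": len(component.query_nodes),
            "scale_free_before_augmentation": pre_diag.verdict,
            "scale_free_after_augmentation": post_diag.verdict,
            "k_top": report.k_top,
            "hubs": report.hubs,
            "bottlenecks": report.bottlenecks,
            "hub_bottlenecks": report.hub_bottlenecks,
            "crucial_genes": report.crucial_genes,
            "n_significant_terms": sum(r.significant for r in results),
            "n_term_clusters": n_clusters,
        }
        with open(out("report.json"), "w") as fh:
            json.dump(run_report, fh, indent=2, sort_keys=True)
        logger.info("[report] %s", json.dumps(run_report, sort_keys=True))
        return run_report
    except Exception as exc:  # clean up partial outputs, re-raise with the stage name
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
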