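# Methods

## Overview

`hubnet` prioritizes disease-associated genes by combining two filters: a
statistical one (differential expression between cases and controls) and a
topological one (centrality in the protein–protein interaction network built
around the differentially expressed genes). The output is a small set of
"crucial" genes — hubs, bottlenecks and hub-bottlenecks — plus an
over-representation profile of the annotation terms they populate.

## Differential expression

Each gene is tested with a Welch two-sample *t*-test on log₂ expression
values; the effect is log₂FC = mean(case) − mean(control) and the reported
fold change is two-sided, FC = 2^|log₂FC|, so up- and down-regulation are
treated symmetrically. Benjamini–Hochberg *q*-values are computed across all
tested genes and reported alongside, but the significance filter itself uses
the **raw** *p*-value: a gene is significant iff FC > 2 (strict) and
*p* ≤ 0.05 (inclusive). Gene ranking and the top-250 selection order by
(*p*, gene id), making ties deterministic.

Assumptions and edge cases:

- groups are independent with possibly unequal variances (hence Welch rather
  than pooled *t*); each group needs ≥ 2 samples;
- a gene with zero variance in both groups gets *p* = 1 when the means are
  equal and *p* clamped to 1e-300 when they differ, keeping the ranking
  well-defined without emitting zeros;
- moderated-*t* shrinkage (limma-style) is deliberately not implemented; with
  20 + 20 samples the per-gene variance is estimated well enough that
  shrinkage changes little, and the package stays free of linear-model
  machinery. Users comparing against moderated-*t* (limma-based) output
  should expect small numerical differences in *p*-values.

Input QC mirrors the usual normalized-series boxplot check: the run passes
comparability iff every per-sample median lies within `tol` (default 0.5 log₂
units) of the median of per-sample medians. Missing cells (blank/`NA`) are
imputed with the gene's row median; genes with > 20 % missing are dropped
with a warning. Matrices whose maximum exceeds 50 are assumed linear-scale
and log2(x+1)-transformed (overridable).

## Network construction

The interaction database is a STRING `protein.links`-dialect edge list with
integer confidence scores in [0, 1000]; edges below `score_threshold`
(default 400, "medium confidence") are discarded, duplicates keep the maximum
score, self-loops are dropped. The database keeps the set of all node ids
seen in the file as its *universe*, so a query gene whose only interactions
are sub-threshold counts as *recognized but isolated* — exactly the genes
later removed with the non-main components.

First-neighbor augmentation ranks candidate nodes (database nodes adjacent to
≥ 1 query gene, query genes excluded) by: number of distinct query
connections (desc), summed confidence of query-incident edges (desc), node id
(asc), and adds the top *m* (default 20) with all database edges among the
enlarged node set materialized. The ranking rule is this package's own
deterministic stand-in for the opaque neighbor selection of interactive
network tools; it favors the interactors most relevant to the query set and
makes reruns byte-identical.

The main connected component is the largest component by node count (ties
broken toward the component containing the lexicographically smallest id);
everything else is reported as excluded.

A scale-free diagnostic fits log₁₀ P(k) against log₁₀ k by least squares over
observed degrees k ≥ 1 (histogram normalized over all nodes). The verdict is
"scale-free-like" iff slope ∈ [−3, −1], r² ≥ 0.7 and the isolated fraction is
≤ 0.1; an isolated fraction > 0.3 is additionally flagged as weak
interactions. These cutoffs are heuristics exposed in the module constants —
degree-histogram regression is a coarse instrument, and the verdict is meant
as a QC annotation, not an inferential claim. On 500-node
preferential-attachment graphs (attachment 2) the rule returns
"scale-free-like" in ≥ 8 of 10 seeds (the measured exponent of such a fit is
typically ≈ 1.7–1.9, shallower than the theoretical 3 because the raw
histogram tail is noisy).

## Centrality

Degree K(v) is the number of distinct neighbors. Betweenness uses Brandes'
exact algorithm (BFS shortest-path counts plus reverse dependency
accumulation) on the **unweighted** graph — confidence scores weight nothing
here, matching the convention of the interactive network analyzers whose
printed BC values sit on the 0–1 scale. Normalization divides raw
betweenness by (n−1)(n−2)/2 on the component, the convention inferred from
the magnitude of published per-node BC values (e.g. a 59-node component with
per-node BC around 0.005–0.07); this inference is a documented choice, and
values are reported at full precision with a 3-decimal convenience column.
The test suite verifies Brandes output against an independent brute-force
enumeration of all shortest paths on random graphs up to 50 nodes, plus the
conservation identities ΣK = 2|E| and Σ raw B(v) = Σ_pairs (d(s,t) − 1).

## Hub/bottleneck classification

k_top = ⌈fraction × (number of query genes in the component)⌉, with fraction
defaulting to 0.10. The decile is taken over the **query genes only**: the
neighbor nodes exist to connect the network and are never classified, and
with 39 query genes this yields ⌈3.9⌉ = 4 hubs and 4 bottlenecks (computing
over all 59 component nodes would give 6 — the query-restricted reading is
the one consistent with the worked example shipped in
`synthetic_data.paper_fixture`). Hubs sort by (K desc, BC desc, id asc),
bottlenecks by (BC desc, K desc, id asc); ceiling (not floor/round) is the
only rounding consistent with 39 → 4. Crucial genes are the union of the two
lists, hub-bottlenecks the intersection.

## Enrichment

For each annotation term with overlap k ≥ `min_overlap` (default 2):
p = P[X ≥ k] with X ~ Hypergeometric(N, K_term, n_query), where N is the
universe size (union of all GMT term genes, optionally intersected with a
user background — annotation files carry no universe of their own, so the
union is the least-assumption default), BH adjustment across tested terms,
significance at raw p ≤ 0.05. Significant terms are grouped by Cohen's kappa
between their gene-membership indicator vectors over the universe; terms with
κ ≥ 0.4 (the conventional default for kappa-based term grouping) are linked
and connected components form the clusters, labeled by their smallest-p term.
A term covering the whole universe makes the 2×2 table degenerate; its kappa
is defined as 0 with a warning. The number of clusters is whatever the data
give — it is never forced to a preset count.

## Synthetic data generator

The generator emulates a two-tissue pediatric case/control expression study
and its downstream network analysis at the study's own scale — defaults are
20 + 20 samples, 2000 genes, 81 planted DE genes, 69 of them recognized by
the database, 20 added neighbors, and a 39-query-gene main component:

- **Expression**: per-gene baseline ~ N(8, 1) log₂ units, i.i.d. N(0, 0.25)
  noise (a typical within-group SD for normalized array/RNA intensities), and
  planted |log₂FC| uniform on [1.2, 3] with random sign — above the FC > 2
  line by construction and ≈ 10–15 within-group SDs of the group-mean
  difference, so recovery power is essentially 1 while null genes stay at the
  nominal 5 % false-positive rate.
- **Database**: a 400-node preferential-attachment backbone (attachment 2)
  whose 20 highest-degree nodes act as anchors. Each ordinary connected query
  gene attaches to two ring-consecutive anchors (guaranteeing one connected
  core of 39 query + 20 anchor nodes) plus one unique non-anchor node; the
  designated target gene attaches to 12 distinct anchors, giving it strictly
  maximal degree and, in practice, maximal betweenness among query genes.
  30 query genes receive only sub-threshold edges (recognized but isolated)
  and 12 are absent from the file. Anchor construction makes the top-20
  neighbor candidates exactly the anchors, so the pipeline's main component
  reproduces the 39 + 20 = 59 shape deterministically.
- **Annotations**: 3 blocks × 6 terms sharing a 10-gene core per block with 2
  pool-private extras per term (within-block κ ≈ 0.8, cross-block κ ≈ 0);
  background terms partition the remaining genes so the universe covers the
  full list. Focus genes (the intended enrichment query) are distributed
  round-robin into block cores so each block's terms overlap them.

All randomness flows from a single config seed through named per-stage
`numpy` generators; no global state is touched, and generators are pure
functions of their config (asserted byte-level in tests).

What the generator does **not** emulate — and hence what passing tests do not
show about real data: probe/platform effects, batch structure,
tissue-specific expression, correlated genes, the literature-derived topology
of a curated interactome, or an ontology DAG with propagated annotations.
The planted-target recovery result demonstrates that the pipeline's plumbing
and decision rules are correct, not that the statistical filters would rank
any particular biological gene first.

## Numerical and design choices

- p-values are clamped to [1e-300, 1]; hypergeometric tails come from
  `scipy.stats.hypergeom.sf` at double precision.
- All orderings that affect output carry an explicit final tie-break on the
  identifier, so every artifact on disk is byte-reproducible.
- The per-stage problem sizes used by the tests and the acceptance script
  (2000-gene matrices, ≤ 50-node oracle graphs, 10-seed repetitions,
  400-node backbones) were chosen as the smallest sizes at which the
  calibration quantities (type-I error, power, recovery rates) are stable;
  they run in seconds.
- The pipeline treats one expression matrix per run; stratified (per-tissue)
  analyses are left to the caller, who can run the pipeline once per stratum.
- Whether an expression study's "p ≤ 0.05" filter should use adjusted
  p-values is study-dependent; this package uses the raw p-value for the
  filter and always reports BH q alongside.

## Known limitations

- Welch *t* on log₂ values assumes approximate normality; heavy-tailed counts
  should be transformed (or analyzed with a count model) upstream.
- Betweenness is exact but O(nm); the intended scale is the post-filter
  component (tens to hundreds of nodes), not whole interactomes.
- Identifier namespaces are not mapped: the expression matrix, database and
  GMT must already share gene symbols.
- The scale-free verdict is a heuristic QC label; rigorous power-law testing
  (e.g. likelihood-ratio comparisons against alternatives) is out of scope.
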