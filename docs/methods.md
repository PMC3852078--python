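# Methods

This note documents the statistical models, algorithms and numerical choices
behind `crossnet`, what the synthetic generators do and do not emulate, and
the design decisions taken where several readings were defensible.

## Candidate gene selection

Each probe is tested with the two-sample Student's *t* test (pooled
variance, df = n₁ + n₂ − 2, two-sided).  Welch's test is available via
`equal_var=False` for heteroscedastic data, but the pooled test is the
default because the named procedure in this literature is Student's test
and because the Gaussian equal-variance generator makes its calibration
exact.  A probe that is constant and identical in both groups gets
(t, p) = (0, 1) rather than NaN, so gene counts are stable; a zero-variance
separation maps to the smallest positive float rather than p = 0, keeping p
in (0, 1].

Probes collapse to genes by **minimum p** (direction from the minimal-p
probe): any significant probe flags its gene, which matches threshold-style
selection semantics.  A mean-p alternative is exposed via
`aggregate="mean"`.  The two selection rules are:

* `select_by_pvalue`: aggregated p < α, default α = 0.05, **no**
  multiple-testing correction — deliberately, because the workflow treats
  this as a screening step; FDR control is applied later, at enrichment.
* `select_top_fraction`: genes ranked by t; ⌊f·G⌋ per tail, default
  f = 0.01.  Ties break by lexicographic gene symbol, and both tails come
  from one descending sort of (t, symbol), which makes the over/under sets
  provably disjoint whenever G ≥ 2⌊f·G⌋ (smaller inputs raise a
  degenerate-input error).

Merging candidate sets never collapses conflicting calls: a gene called
"over" by one source and "under" by another keeps both (label, direction)
pairs in its provenance and is summarised as "mixed".

## Query networks

For queries *Q* over interactome *G* (undirected, simple, self-loop-free;
symbols uppercased on load by default to avoid silent case mismatches):

* QQPPI = G[Q], the induced subgraph on the queries.
* L1PPI = G[Q ∪ N(Q)] — the **full induced subgraph**, i.e.
  mediator–mediator edges are retained.  This is the reading under which
  clique analysis on the extended network can produce cliques spanning
  mediators; a star-only variant (`mediator_edges=False`) keeps only
  query-incident edges for users who want strictly query-anchored links.
* Queries absent from the interactome stay as isolated nodes.  They carry
  annotation, and — importantly for the connectivity null — a random draw
  from a genome-wide symbol universe must be allowed to contain genes with
  no interactions at all.

An "interactor" is a mediator (non-query L1PPI node).  Whether query genes
reached by another list should also count is genuinely ambiguous in this
kind of analysis, so `mediator_overlap(include_queries=True)` computes the
alternative convention; the default reports mediators only.
`MediatorOverlap.from_counts` reproduces the overlap percentages from
already-tabulated counts, for worked examples where only the counts are
known.

## Topology

* Connected "subgraphs" count components with ≥ 2 nodes by default — an
  edgeless gene is not a network.  `min_size=1` counts every component,
  since published subgraph counts do not always state the convention.
* Maximal cliques come from Bron–Kerbosch with pivoting; the clique-k
  subnetwork enumerates all k-subsets of maximal cliques of size ≥ k and
  unions their vertices and within-clique edges.  Outputs are canonically
  ordered (size descending, then lexicographic) so results are diff-stable.
* Betweenness is exact (Brandes), reported as unnormalized pair counts so a
  5-star's center scores C(4,2) = 6.  Closeness is **harmonic** centrality
  scaled by 1/(n−1): it is well defined on the disconnected graphs that
  QQPPI networks typically are, lies in [0, 1], and gives isolated nodes 0.
  Gene ranking sorts by (betweenness desc, expression score desc, symbol).
* MCL iterates a column-stochastic flow matrix (adjacency + self-loops of
  weight 1) by expansion (matrix power, e = 2) then inflation (entrywise
  power r, column renormalization), pruning entries < 10⁻⁵, until the
  maximum entry change is < 10⁻⁸ or 100 iterations (non-convergence is
  flagged, best partition returned).  Clusters are read from attractor rows
  (positive diagonal); a node supported by several attractors joins the
  lexicographically smallest one, so the result is a deterministic
  partition.  Defaults (r = 2.0, e = 2) follow the canonical description of
  the algorithm; the upstream literature does not publish the inflation it
  used, so it is a parameter, not a claim.

## Connectivity null

Each of `n_draws` (default 5000) draws samples `n_query` symbols uniformly
**without replacement** from the provided universe — including symbols
absent from the interactome, because a genome-wide symbol list necessarily
contains non-interacting genes — builds the QQPPI, and records (subgraph
count, edge count).  Both statistics are summarised; the headline number is
`percentile_top` = 100·#{draws ≥ observed}/n_draws, the observed network's
rank in the null.  Because a rank of exactly zero is possible and the raw
fraction is not a valid p-value, the add-one empirical p (r+1)/(n+1) is
reported alongside for inferential use.  Draw statistics are computed on a
CSR adjacency submatrix (edge count = nnz/2; components via sparse
connected-components), which keeps 5000 draws on a ~3000-node interactome
in seconds.

With ties (the statistics are integers), `percentile_top/100` under
self-calibration is slightly super-uniform at the tie mass; the calibration
test uses a graph dense enough that the edge statistic spreads over many
values, making the discreteness negligible at the tested resolution.

## Enrichment and FDR

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) with population |U|, successes |S∩U|, draws |Q∩U|; it agrees with
Fisher's one-sided exact test by construction.  The background universe
matters and no single default is defensible, so the pipeline uses
(catalog genes ∪ interactome nodes) ∩ provided universe and the library
function takes the universe explicitly.  Benjamini–Hochberg is the step-up
q_(i) = min_{j≥i} m·p_(j)/j capped at 1, input order preserved; inputs must
lie in (0, 1].

Complex matching is scored rather than exact-containment — published
complex catalogs share members with, not equal, network cliques — with a
minimum overlap of 2 genes, the hypergeometric p (same code path as
enrichment), the overlap coefficient |clique∩set|/|clique|, and BH across
all reported (clique, set) pairs.  Drug mapping is a pure symbol join
grouped by drug; drug-class vocabulary is free text from the input table.

## Synthetic data: what it emulates, what it does not

`gen_expression` draws null genes i.i.d. Normal(baseline, σ²) in both
groups and shifts a planted gene's case mean by ±d·σ (Cohen's d).  This
matches the t-test's assumptions exactly, which is the point: selection
power has a noncentral-t closed form and type-I calibration is binomial, so
test expectations are derivable rather than tuned.  It does **not** model
microarray artifacts — probe cross-hybridization, intensity-dependent
variance, normalization effects, gene–gene correlation — so passing tests
certify the algorithmics and calibration of the pipeline, not robustness to
real array noise.  One probe per gene by default; `probes_per_gene=k`
exercises the aggregation rule.

`gen_interactome` offers Erdős–Rényi G(n, p) and Barabási–Albert
preferential attachment, with planted cliques overlaid; neither reproduces
the real interactome's degree mixing or clustering beyond what those models
give.  `gen_catalog` plants enriched sets verbatim among random sets;
`gen_drug_table` emits the four-column drug/gene/name/class schema.

The `paper-shaped` bundle preset is sized like a two-disease microarray
study: a 23-vs-19 dataset over 2000 genes tuned so that p < 0.05 selection
yields roughly 470 candidates (planted d = 2 signal plus the expected
type-I calls), a 225-vs-220 dataset over 12624 genes from which the top-1%
rule takes 126 + 126, a ~3000-node interactome (mean degree ≈ 7) with
planted 4- and 5-cliques, a 32560-symbol universe for the null, and a
5000-draw null.  The `smoke` preset is a miniature (300/600 genes, 300
nodes, 200 draws) used by the test suite and examples so the full pipeline
runs in seconds.

## Pipeline determinism

A single config seed is split per stage as
blake2s("{seed}:{stage}") mod 2³¹, so inserting or reordering stages cannot
silently shift another stage's stream, and every derived seed fits common
32-bit seed APIs.  The run manifest records config, per-stage parameters
and sha256 checksums of all outputs; reruns are bit-identical.

## Known limitations

* Enrichment results depend strongly on the chosen background universe;
  the package computes, it does not adjudicate.
* The connectivity null samples genes uniformly; it does not match degree
  distributions, so it answers "is this set more wired than a random gene
  set?" not "…than a random set with the same degrees?".
* MCL on large dense networks uses an O(n³) dense iteration; intended for
  the sub-thousand-node query networks this workflow produces.
* Published gene lists from versioned external databases cannot be
  regenerated from synthetic data; the package reproduces procedures and
  their calibration, not historical database snapshots.
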