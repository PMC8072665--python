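# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the design was open.

## Compound screening

Candidate compounds carry two pharmacokinetic covariates: oral
bioavailability (OB, percent) and drug-likeness (DL, unitless in [0, 1]).
The screen keeps OB ≥ 30 and DL ≥ 0.18, both inclusive, with no rounding
before comparison; both cutoffs are arguments. De-duplication is keyed on
the compound identifier, never the display name (stereochemistry strings
make name collisions possible); herb sets are unioned, OB/DL come from the
first occurrence and a conflicting later value is logged rather than
averaged. The census distinguishes *unique compounds* from *compound–herb
assignments* (a compound in three herbs is one compound, three
assignments); equality of the two counts holds exactly when every compound
is single-herb. The packaged BZD table (98 compounds, 113 assignments,
nine herbs) is shipped verbatim with a checksum test; the census never
hard-codes a herb list — it reports whatever herb codes appear in the
input.

Screening is applied before de-duplication. For any table whose duplicate
rows agree on OB/DL (including the packaged one) the order is immaterial.

## Differential expression

The input is a log2 expression matrix with a two-group (case/control)
design; normalization is upstream of this package. Per gene the pooled
variance s²_g with d = n₁ + n₂ − 2 residual df is shrunk towards a prior:

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),
    t_g = log₂FC_g / sqrt(s̃²_g (1/n₁ + 1/n₂)),  df = d₀ + d.

The hyperparameters are fitted by moment matching on
e_g = log s²_g − ψ(d/2) + log(d/2): under the scaled-F model
s² ~ s₀²·F(d, d₀), Var[e] = ψ′(d/2) + ψ′(d₀/2) and
E[e] = log s₀² − ψ(d₀/2) + log(d₀/2). The trigamma equation is inverted by
Newton iteration (relative tolerance 1e-10). When the observed dispersion
of log s² does not exceed the chi-square sampling noise, d₀ = ∞ and
s₀² = mean(s²) — the unbiased estimate under s² ~ s₀²χ²_d/d, which also
returns exactly c when every variance equals c; the statistic then reduces
to a z-test. d₀ = 0 is accepted as the explicit no-shrinkage limit and
reproduces the ordinary pooled t to 1e-10 (tested). Genes with zero
posterior variance are flagged and excluded from calls instead of being
assigned p = 0. One test validates the whole path (prior, t, p) against
Bioconductor limma's eBayes on a shared matrix, to ~1e-8.

Significance is p < 0.05 (strict) and |log₂FC| > 0.05 (strict). The fold
threshold is unusually permissive as a screening rule; it is deliberately
the default here and configurable (`lfc_min`), as is an FDR-based criterion
(`use_fdr`) and a plain Welch alternative (`test="welch"`). Designs are
treated as unpaired throughout; paired structures are not modelled. Each
profile is analysed once — no cross-analysis p-value combination is
attempted. Duplicate gene symbols keep the first occurrence, logged.

## Network construction and the centrality cascade

All graphs are simple and undirected; interaction lists (2- or 3-column,
SIF-compatible) are de-duplicated on read and self-loops dropped with a
logged count. The compound–target network joins compounds to their targets
restricted to the disease-gene set, dropping isolated vertices. Seed
networks are one-hop expansions: the subgraph induced by the seeds present
in the interactome plus their first neighbours. Network intersection is
set-intersection of both nodes and edges.

Centrality definitions (scored per node):

- **DC** — degree.
- **BC** — Brandes betweenness, unnormalized, each unordered pair counted
  once, endpoints excluded. On trees this equals the count of pairs whose
  unique path passes through the node (tested against path enumeration).
- **CCT** — Wasserman–Faust composite closeness
  (r/(n−1))·(r/Σdist), r = reachable nodes; equals the classical
  (n−1)/Σdist on connected graphs and handles disconnected ones gracefully.
- **EC** — principal eigenvector of the adjacency matrix, non-negative,
  L2-normalized, computed by power iteration on the largest connected
  component (tolerance 1e-10, max 1e5 iterations); other nodes score 0.
  The iteration multiplies by A + I rather than A: the Perron vector is
  unchanged and the shift makes the matrix primitive, so the iteration
  cannot oscillate on bipartite components.
- **LAC** — mean degree of the node's neighbours within the subgraph
  induced by those neighbours; 0 for isolated nodes.
- **NC** — Σ over incident edges of the edge clustering coefficient
  z/min(deg−1, deg−1) (z = common neighbours); a zero denominator (leaf
  endpoint) contributes 0.

The screen runs in two stages. Stage 1 cuts on degree: an absolute cutoff
(`dc_abs`, reproducing published "DC > 61"-style rules) or, by default,
2.0 × the median degree — an absolute cutoff borrowed from one dataset does
not transfer to graphs of a different scale. Stage 2 recomputes the
configured metrics (default: BC, CCT, EC, LAC, NC) **on the stage-1
subgraph** and keeps nodes strictly above every metric's median there.
Strict inequalities are kept exactly as published conventions print them
("BC > 75.38397"); the documented consequence is that fully tied inputs
(e.g. a complete graph) eliminate everything. Medians use the
midpoint-of-two-middle-values convention. Every stage's node/edge counts
and computed thresholds are recorded in the cascade result.

## Over-representation analysis

Annotations are flat GMT gene sets in four categories (BP, CC, MF,
PATHWAY); ontology-graph propagation is out of scope — flat sets keep the
statistic exact and testable against enumeration. The per-term p-value is
the hypergeometric upper tail P(X ≥ k) for k query hits in a K-gene term,
query size n, universe N (default universe: the union of database genes;
an explicit background can be supplied). Terms with zero hits are excluded
*before* adjustment, so the tested family is "terms with at least one hit"
(logged); BH step-up FDR is applied within each category separately,
mirroring per-category reporting conventions. Records sort by p, ties by
fold then term id, and top-k selection takes the first k with FDR < 0.05
(strict).

## Integration

Venn reports decompose 2–6 named sets into their exact exclusive regions
(the regions provably partition the union; tested as a property). The
"at least k of m" expansion generalises the published practice of widening
a three-way intersection to genes shared by two profiles (k = 2 default).
The gene–pathway network connects candidate genes to the significant terms
containing them; the core gene is the degree maximum with *all* ties
reported. Key pathways are the term ids significant in every profile,
reported with per-profile p/FDR side by side. Both evidence tracks (target
genes; topology-screened genes) are exposed without a built-in winner
declaration — nominating one pathway over another is an interpretive step,
not an algorithmic one.

The run report is a single JSON with no timestamps; a fixed seed and
config produce byte-identical output (tested). A missing stage is marked
`"absent"`, never silently dropped. The report validates against a schema
shipped with the package.

## The synthetic-data generator

One scenario seed drives independent per-component substreams
(`default_rng([seed, offset])`), so regenerating one artifact never
perturbs the others, and everything is byte-reproducible.

- **Expression** (default 2,000 genes, 12 vs 12 samples): per-gene baseline
  means ~ Normal(7, 1.5) on the log2 scale, i.i.d. Normal(0, σ²) noise with
  σ = 0.5, and 300 planted genes shifted ±δ in cases (δ = 1.0, half up,
  half down). The defaults put the planted effect far above the permissive
  |log₂FC| > 0.05 call threshold, so recovery tests are sharp. δ = 0 gives
  a calibrated null (p < 0.05 rate within its binomial envelope, tested).
- **Interactome** (default 500 nodes): a Barabási–Albert base (m = 3) with
  a near-clique planted on the 20 highest-degree nodes (pairwise wiring
  probability 0.9, plus 9 uniform attachments each). Hosting the module on
  the hubs is what makes it a genuinely *high-centrality* core — the
  standard picture of a disease module at interactome hubs; a module
  planted on random low-degree vertices cannot out-rank scale-free hubs on
  degree, and a median-based screen would then face an irreducible
  precision/recall trade-off. Degree distributions remain heavy-tailed
  (max ≥ 5 × median, tested).
- **Annotations** (default 200 terms, sizes 10–60): background terms drawn
  uniformly; one planted term per category containing the core (padded to
  an in-range size).
- **Compounds** (default 120): OB ~ U(10, 90), DL ~ Beta(2, 2); 15% of
  compounds belong to 2–3 herbs and are emitted once per herb, exercising
  de-duplication; targets draw from the interactome nodes with probability
  0.3 of hitting the core, giving downstream screening its signal.
- **Scenario**: each profile's planted DE set contains every core node (the
  shared disease module) plus a per-profile random remainder, so the
  planted pathway is recoverable from all profiles.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, paired designs, correlated gene expression, the overlap
structure of real GO terms, or literature-biased interactome degree. A
pipeline that recovers planted structure here is verified as *correctly
implementing its own model*, not as robust to those real-data features.

Default sizes (2,000 genes, 500-node interactome, 200 terms, 120
compounds, 3 profiles) keep a full run under a second on one CPU, so
recovery statistics over 20 seeds are cheap.

## Known limitations

- The cascade's strict median rule degenerates on score-tied graphs by
  design; callers screening near-regular graphs should use absolute
  thresholds.
- Closeness comparisons across graphs of different order are not
  meaningful off the connected case (the n-dependent factor); the cascade
  only ever compares scores within one graph.
- The enrichment universe default (union of database genes) is the right
  null for database-driven queries but should be replaced with the assay
  background when one exists.
- OB and DL are inputs, never computed from structure; interaction
  databases are never queried — all external data arrives as files.
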