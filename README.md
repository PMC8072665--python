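# netpharm

Network-pharmacology inference for multi-herb formulations.

Traditional Chinese medicine decoctions act through many compounds hitting
many protein targets at once. Network pharmacology infers *which* targets and
pathways matter by chaining together: ADME screening of the formulation's
candidate compounds, differential-expression screening of disease expression
profiles, compound–target network construction, topological screening of the
protein–protein interaction (PPI) neighbourhood shared by formulation targets
and disease genes, and over-representation analysis of the surviving targets
— then intersecting the evidence across several independent expression
profiles. `netpharm` implements that whole chain as a tested, scriptable
Python pipeline, with a synthetic-data generator (planted differentially
expressed genes, a planted high-centrality PPI core, a planted enriched
pathway) so every stage can be verified offline against known ground truth.

It ships the candidate-compound table of Bushen Zhuangjin decoction (BZD), a
ten-herb formulation used against osteoarthritis, screened from TCMSP at the
conventional thresholds — the package's one piece of real data.

## The statistics at the core

**ADME screen.** Keep compounds with oral bioavailability OB ≥ 30% and
drug-likeness DL ≥ 0.18 (inclusive), de-duplicate on compound id merging
herb assignments, and keep the census honest: unique compounds vs.
compound–herb assignments.

**Moderated t.** Per gene, the pooled two-group variance s²_g (d residual
df) is shrunk towards an empirical-Bayes prior (d₀, s₀²) fitted by moment
matching on log s²_g (trigamma inversion by Newton iteration):

    s̃²_g = (d₀·s₀² + d·s²_g) / (d₀ + d)
    t_g  = log₂FC_g / √(s̃²_g·(1/n₁ + 1/n₂)),   df = d₀ + d

Genes are called at p < 0.05 and |log₂FC| > 0.05 (both strict, both
configurable). The implementation is cross-checked against Bioconductor
limma to ~1e-8 in the test suite.

**Centrality cascade.** On the intersection of the one-hop PPI
neighbourhoods of formulation targets and disease genes, stage 1 keeps nodes
with degree (DC) strictly above a cutoff (absolute, or factor × median;
default 2 × median); stage 2 recomputes betweenness (BC, Brandes,
unordered pairs), Wasserman–Faust closeness (CCT), eigenvector centrality
(EC, power iteration on the largest component), local average connectivity
(LAC) and edge-clustering network centrality (NC) on the stage-1 subgraph
and keeps nodes strictly above *every* metric's median.

**Over-representation.** Hypergeometric upper tail per gene-set term,
Benjamini–Hochberg FDR per category (BP/CC/MF/PATHWAY), FDR < 0.05, top 20.

**Integration.** Venn region decomposition across profiles, the
"at least 2 of m profiles" expansion, gene–pathway bipartite networks with
core-gene nomination by degree, and key pathways = terms significant in
every profile.

## Worked example

Generate a three-profile synthetic study and run the full chain:

```sh
netpharm simulate scenario --seed 7
```

```python
from netpharm.pipeline import PipelineConfig, run_all, summarize_report
cfg = PipelineConfig.for_scenario("scenario", seed=7)
print(summarize_report(run_all(cfg)))
```

```
config a1526802633f1bd0  seed 7
compounds: 148 raw rows -> 107 pass ADME -> 90 unique (107 herb assignments)
profile_1: 199 up / 182 down DE genes; CT net 138 nodes / 188 edges; cascade -> 17 targets; 4 enriched terms
profile_2: 194 up / 200 down DE genes; CT net 147 nodes / 201 edges; cascade -> 21 targets; 4 enriched terms
profile_3: 193 up / 196 down DE genes; CT net 143 nodes / 192 edges; cascade -> 20 targets; 4 enriched terms
key pathways (all profiles): PLANT_PATHWAY
planted-core recovery: precision 0.984, recall 0.950; planted pathway recovered: True
```

Reading it: of 148 raw compound rows, 107 pass the OB/DL screen and collapse
to 90 unique compounds; each profile yields ~390 differentially expressed
genes (300 planted plus the expected false calls of the permissive screen);
the compound–target networks and the centrality cascade reduce each profile
to ~20 screened targets; enrichment finds the planted term in every
category; and the planted pathway is the single term significant in all
three profiles — the pipeline's "key pathway" — while the cascade recovered
the planted 20-node PPI core at precision 0.98 / recall 0.95.

The packaged BZD table can be audited directly:

```sh
netpharm audit-compounds   # 98 unique compounds, 113 herb assignments
```

Per-stage subcommands (`compounds`, `degs`, `ctnet`, `ppi-screen`,
`enrich`, `run-all`) operate on plain TSV/CSV/SIF/GMT/JSON files; see
`netpharm --help`.

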