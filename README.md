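# pclstx

Cross-species transcriptomics pipeline for nutrient-induced steatosis in
precision-cut liver slices (PCLS).

## The problem

PCLS are thin, viable sections of liver tissue cultured *ex vivo*. Steatosis
(fatty liver) can be induced in them by incrementally supplementing the
culture medium with sugars (glucose, fructose), insulin and fatty acids
(oleate, palmitate). A two-species assay cultures slices from human donors
and from mice under a mirrored factorial design — 8 media × 2 timepoints
(24 h, 48 h) — and profiles each pool by RNA-seq. The analysis question is
which genes respond consistently to the nutrient conditions, which respond
the same way in both species, and which diverge.

The statistical difficulty is that human donor tissue is heterogeneous:
between-donor variance dominates the human expression data and swamps the
design factors, whereas the inbred mouse arm is driven by time in culture
and medium. `pclstx` implements the paired, donor-blocked analysis this
design calls for, plus a seeded synthetic-data generator that emulates the
study's statistical structure so every stage can be validated against known
ground truth without any external download.

## What it computes

For each species, every non-control medium is contrasted against the
time-matched control within subject. Per gene *g* and contrast *c*:

- `log2FC_gc = mean_s(x_g,test(s) − x_g,CTR(s))` over subjects *s* with both
  samples, on log2 counts-per-million;
- a moderated t-statistic `t = log2FC / sqrt(s̃²_g / n)` with empirical-Bayes
  variance shrinkage `s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d)`, the prior `(d₀, s₀²)`
  estimated by moment-matching on `log s²_g`;
- Benjamini–Hochberg adjusted p-values within each contrast.

Each contrast is then collapsed to a **sign**: `sign(log2FC)` if
`p_adj ≤ 0.05` and `|log2FC| ≥ 0.5`, else 0. Per gene:

- **sum of signs** over a species' 14 contrasts (range ±14) and over the
  combined 28 human + mouse contrasts (range ±28) — consistent regulation;
- **divergence** = Σ_c |sign_h(c) − sign_m(c)| (range 0–28) — opposite
  regulation between species;
- **weighted score** = |Σ_c log2FC_c · (−log10 p_adj,c)| — ranks selected
  genes (|combined sum| ≥ 8) by magnitude and significance.

A separate concordance track correlates ortholog pairs' condition-group
median expression (after donor centering) across the 16 groups, per gene and
per condition, and rank-correlates per-pair expression correlation against
% global sequence identity. QC utilities provide exact PCA with a robust
MAD-based outlier screen, complete-linkage Euclidean clustering on log-CPM,
and per-condition coefficients of variation.

## Worked example

```python
from pclstx import (SimulationConfig, simulate_study, simulate_ortholog_map,
                    PairedContrastModel, build_gene_scores, select_and_rank)

cfg = SimulationConfig(n_genes=800, seed=7)
study = simulate_study(cfg)          # both species, shared truth ledger
results = {
    sp: PairedContrastModel.from_counts(study.counts[sp], study.metadata[sp]).fit()
    for sp in ("human", "mouse")
}
print(results["human"].summary())
```

```
Paired contrast differential expression
  genes: 800   contrasts: 14
  cutoffs: |log2FC| >= 0.5, BH p_adj <= 0.05

  contrast     n_pairs    n_up  n_down
  G_24h              7       1       0
  G_48h              7       1       1
  F_24h              7       3       1
  F_48h              7       1       2
  GF_24h             7      25      31
  ...
  GFIPO_48h          7      30      44
```

The counts of significant genes grow with the nutrient dose, as planted:
dose-1 media (G, F) carry a 0.5 log2 effect on responsive genes, GFIPO a
2.5 log2 effect. Scoring the two species jointly:

```python
pairs = simulate_ortholog_map(cfg.n_genes, seed=7, truth=study.truth)
scores = select_and_rank(build_gene_scores(results["human"], results["mouse"], pairs))
print(scores[scores["selected"] == 1].head(5))
```

```
  gene_h  sum_signs_h  sum_signs_m  sum_signs_combined  divergence  sum_score_h  rank
HG000161           -9           -8                 -17           1   270.033543     1
HG000398          -11           -8                 -19           3   241.985300     2
HG000608          -10           -9                 -19           1   238.341506     3
HG000113          -10          -10                 -20           0   231.500304     4
HG000401          -11           -9                 -20           2   228.122643     5
```

All five top-ranked genes belong to the generator's `shared_nutrient` truth
class: consistently regulated in both species across conditions, which is
exactly what the combined sum-of-signs selection is built to find. High
`divergence` values instead flag genes the two species regulate in opposite
directions.

The same pipeline runs from the shell:

```bash
pclstx all --seed 7 --outdir out/       # simulate → qc → de → score → xspecies
```

writing provenance-stamped TSVs and a `manifest.json` of output hashes
(byte-identical on re-run with the same config and seed).

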