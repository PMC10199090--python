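# Methods

## The design being modelled

The assay cultures precision-cut liver slices from 7 human donors and 5 mice
in 8 media — a 25 mM-glucose control (CTR) and seven incremental nutrient
supplementations (G: 36 mM glucose; F: +5 mM fructose; GF: both; GFI: +1 nM
insulin; GFIO: +480 µM oleate; GFIP: +240 µM palmitate; GFIPO: both fatty
acids) — each sampled at 24 h and 48 h. That is 112 potential human samples
and 80 mouse samples. Six human samples never reached sequencing and seven
sequenced human samples were excluded as PCA outliers, leaving 99; all 80
mouse samples are retained. `pclstx.design` encodes the grid, the staged
exclusions and the 14-per-species contrast set (each non-CTR medium vs the
time-matched CTR). The per-condition identities of the six pre-sequencing
failures are reconstructed from the design table's per-donor totals; they
are shipped as an explicit fixture (`PRESEQ_FAILURES`) rather than
hard-coded into the enumeration, because the evidence is a margin
calculation, not a direct statement. Which single failure was due to low RNA
yield is unknown; the `low_yield` label on one of them is a convention.

## Differential expression model

Counts are transformed to `log2((count + 0.5) / (libsize + 1) × 1e6)`
(pseudocount 0.5, column-sum library sizes). Genes never exceeding 10 counts
in any sample are dropped before model fit (the threshold reading "detected
in at least one sample" was chosen among per-sample/per-condition/summed
alternatives; it is configurable).

Each contrast is a paired comparison: per subject the difference of the
test-medium and control log-CPM values, pooled by the mean. Pairing by
subject removes additive donor effects exactly — the operation the dominant
human donor variance requires. Subjects missing either member of a pair are
dropped from that contrast (pair-wise deletion); contrasts with fewer than
two complete pairs are emitted with missing statistics rather than silently
skipped.

Per-gene difference variances (d = n_pairs − 1 df) are shrunk toward a
common prior under the scaled-F hierarchical model: with
`e_g = log s²_g − ψ(d/2) + log(d/2)`, the prior df `d₀` solves
`ψ′(d₀/2) = var(e) − ψ′(d/2)` (trigamma inversion by Newton's method) and
`s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`; when the observed log-variance
spread is no larger than chi-square sampling noise, `d₀ = ∞` and every gene
is shrunk fully to `s₀²`. The posterior variance
`(d₀s₀² + d·s²)/(d₀ + d)` feeds a two-sided t-test with `d₀ + d` df (normal
in the `d₀ = ∞` limit). This estimator agrees with the Bioconductor
reference implementation of variance squeezing to ~10 significant digits on
fixed draws (frozen in the test suite). With fewer than 10 genes the
moment estimates are meaningless and moderation is skipped with a warning.

BH adjustment is applied within each contrast (the standard per-coefficient
family; the family choice is not dictated by the design). Mean–variance
precision weights are not implemented: the synthetic data are
homoskedastic by construction at the simulated depths, so unweighted
log-CPM plus moderation is the appropriate model here; this is the one
deliberate simplification relative to a full voom-style fit, and it is
confined to `moderate_variances`/`fit_paired_contrasts` behind the same
interface.

## Sign scoring and ranking

A contrast's sign is `sign(log2FC)` iff `p_adj ≤ 0.05` **and**
`|log2FC| ≥ 0.5`, else 0. Both gates are inclusive (≥, ≤) and configurable;
a raw-p-significant but FDR-non-significant contrast scores 0. Sums of signs
per species (±14), combined (±28) and the divergence Σ|sign_h − sign_m|
(0–28) follow directly. The weighted score |Σ log2FC·(−log10 p_adj)| sums
over **all** 14 contrasts by default (non-significant contrasts contribute
small terms); a significant-only mask is available because the alternative
reading cannot be excluded. Adjusted p-values are floored at 1e-300 before
taking logs. Selection keeps |combined sum| ≥ 8 by default (a per-species
gate is exposed), ranks by the chosen weighted score, and breaks ties
lexicographically by gene id so output order is total and reproducible.

## Cross-species concordance

Human expression is donor-centred before any between-species comparison: a
per-gene additive least-squares model (subject with sum-to-zero contrasts +
condition group) whose fitted subject component is subtracted, preserving
group means exactly on balanced data. The mouse arm passes through the same
operator for symmetry. Concordance is then measured three ways: per pair
(Pearson and Spearman across the ≤16 condition-group medians), per
condition (across all ortholog pairs), and against conservation (Spearman
of per-pair Pearson r vs % global sequence identity). Group medians, not
means, are the default per-condition summary (consistent with ranking the
most concordant genes by median expression); means are available. Undefined
correlations (zero variance, <3 shared groups) are emitted as missing with
a reason code, never as 0. Many-to-many ortholog maps are resolved
one-to-one by highest identity, ties by gene id.

## QC

PCA is exact SVD of the gene-centred log-CPM matrix (genes unscaled — the
expression-PCA convention, keeping variance fractions interpretable), with
component signs fixed by making the largest-|loading| gene positive. The
outlier screen flags a sample whose score on any leading component deviates
from the component median by more than `mad_mult` (default 5) robust
standard deviations, using the normal-consistent MAD (×1.4826, as in R's
`mad()`). The original study's screen was visual; this rule is its explicit,
parameterised counterpart, and the study's seven named outliers ship as a
metadata fixture rather than being re-derived. On human-like data with
strong donor structure the screen can legitimately flag whole donors —
donor heterogeneity is precisely what drove the original exclusions — so
calibration claims ("no flags without injected outliers") are made on the
mouse-like arm. Clustering is complete-linkage on Euclidean log-CPM
distance; CVs use the sample SD (n−1) on the linear scale.

## The synthetic study generator

`simulate_study` emulates the statistical structure the analysis assumes,
per gene g, sample s (subject j, medium m, timepoint t):

```
log2 µ_gs = base_g + donor_gj + time_g·1[t=48] + sign_g,species·β·dose(m) + outlier shift
counts_gs ~ NegBin(mean = libsize_s · softmax-normalised 2^(log2 µ_gs), dispersion φ)
```

- Gene classes: 80% null, 10% time-regulated (identical expected effect in
  all 8 media, cancelling in every time-matched contrast), 5% shared
  nutrient-responsive, 5% divergent (opposite signs in the two species).
- Dose model: `dose(m)` counts supplement components beyond CTR
  (G/F = 1, GF = 2, GFI = 3, GFIO/GFIP = 4, GFIPO = 5); the assay is
  incremental but reports no quantitative dose–response, so a component
  count is the neutral choice. `β` defaults to 0.5 log2 per step (dose-1
  media carry a 0.5 log2 effect, GFIPO 2.5). Keeping the responsive
  fraction small and effects moderate also keeps CPM normalisation valid:
  large planted fractions at large effects produce a compositional shift
  (spurious negative log2FC on unaffected genes) that column-sum library
  sizes cannot absorb — a real RNA-seq phenomenon, deliberately kept out of
  the default operating point.
- Donor effects: per gene × subject, SD 1.0 log2 (human) vs 0.2 (mouse) —
  the qualitative contrast between heterogeneous donor tissue and inbred
  mice; time effects N(0, 1.0) on time-class genes.
- Counts: negative binomial with common dispersion 0.1; log-normal library
  sizes, mean 1e6 and CV 0.3 — a desk-scale stand-in for the study's much
  deeper sequencing, chosen so the full pipeline runs in seconds.
- Outliers: optional per-sample gene-wise shifts (SD 2.0 log2 by default),
  identities recorded in the truth ledger. RNA-quality covariation is not
  modelled mechanistically.

What the generator does **not** emulate: transcript lengths (so TPM is out
of scope; log-CPM is the unit throughout), biotype structure, mean–variance
trends across expression strata, correlated genes/pathways, and RIN-driven
quality gradients. Passing tests therefore demonstrate the pipeline's
statistical correctness under the assumed model, not robustness to every
artefact of the deposited data; the `ingest-geo` adapter exists for running
the identical pipeline on real processed matrices.

## Numerical and interface choices

- All randomness flows from one integer seed via `numpy.random.default_rng`;
  identical config ⇒ byte-identical TSVs (the manifest records SHA-256
  hashes, and the provenance hash covers only scientific parameters, not
  file paths).
- TSV dialect: tab-separated, UTF-8, `#` provenance comments, `NA` missing
  values, `%.10g` floats. Gene ids are opaque strings.
- Degenerate inputs are explicit: all-zero count columns, empty condition
  groups, zero-variance correlation vectors, zero-MAD components and
  underpowered contrasts each produce a named error, a warning or a reason
  code — never silent imputation.
- Problem sizes in the test and acceptance runs (1,500–2,500 genes,
  full 112/80-sample designs) were chosen as the smallest at which the
  calibration statistics are stable; all conclusions are recomputed at run
  time from the seeded generator.

## Known limitations

- No precision weights (see above); with strongly depth-varying real
  libraries the moderated fit is less efficient than a weighted one.
- The divergence score treats +1/0 and +1/−1 asymmetrically only through
  the |difference| (1 vs 2); it does not model partial responses.
- The outlier rule is per-component; a sample moderately extreme on several
  components simultaneously is not flagged.
- Sequence identity enters only as a given covariate; computing it from
  sequences is out of scope.
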