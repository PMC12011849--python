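# Methods

`stressmod` re-implements, as a tested and reusable pipeline, a procedure for
discovering a *stress-tolerant* gene co-expression module that discriminates
monocytic myeloid-derived suppressor cells (M-MDSCs) from control myeloid
cells across heterogeneous sample sources. Because the original study's
primary data are external accessions, the package ships a synthetic-data
generator that encodes the study's design and planted ground truth; every
claim the package makes is validated against that ground truth.

## The synthetic experiment

### Single-cell design

The generator emulates a three-arm culture experiment on `n_donors` donors:

- **C** — control monocytes,
- **T** — cytokine-treated (MDSC-inducing) cells,
- **TS** — cytokine-treated cells subsequently serum-starved, of which a
  fraction `resistant_fraction` (default 0.3) survive with their MDSC
  program intact ("resistant" cells). The resistant flag is hidden from the
  pipeline and used only for evaluation.

Counts for gene *g* in cell *c* follow a gamma–Poisson (negative binomial)
law with shared dispersion `nb_dispersion` (default 0.3, a typical droplet
scRNA-seq value) around

```
mu_gc = lib_c * exp(eta_gc) / Z,      Z = sum_g exp(base_g)
```

where `lib_c` is log-normal (`library_size_lognormal`, default mean
log 5000, sd 0.3) and `eta_gc` stacks:

- a per-gene baseline `base_g ~ N(0, 1)`;
- for each planted module, a per-cell latent factor `z_c ~ N(0,1)` scaled by
  `latent_loading` (default 0.5) — this induces the correlation blocks the
  network stage must detect;
- condition effects on module genes (natural-log shifts): `effect_T` in T
  cells, `effect_TS_resistant` / `effect_TS_other` in resistant /
  non-resistant TS cells;
- `ln(2) * log2_dosage` for genes inside a planted copy-number block in
  carrier cells (a random half of the non-control cells by default);
- two fixed accessory programs (below).

Normalizing `eta` by the constant baseline partition function `Z` (rather
than per cell) makes every configured shift exact in expectation — shifted
cells simply carry a slightly larger realized library, as real
perturbations do. Gene baselines and the accessory-program shift vectors
are drawn from a fixed "gene universe" stream keyed only by the universe
size: the biology is shared across simulated experiments, while sampling
noise is controlled by `seed`. Identical configs are bit-reproducible.

### Planted module asymmetry and accessory programs

The default configuration plants three 50-gene modules:

| module | effect_T | effect_TS_resistant | effect_TS_other | class |
|---|---|---|---|---|
| planted_tolerant | 1.5 | 1.5 | 0.0 | tolerant |
| planted_sensitive | 0.9 | 0.0 | 0.9 | sensitive |
| planted_neutral | 0.0 | 0.0 | 0.0 | neutral |

Two structural choices matter and were made deliberately:

1. **The tolerant program is stronger than the sensitive one.** If the two
   programs were symmetric, resistant cells would sit exactly between the
   C and T centroids and no classifier could, even in principle, recognize
   them as "still MDSC-like". The tolerant program being the dominant axis
   of MDSC identity is precisely the biology the analysis is designed to
   exploit.
2. **Non-resistant starved cells mount a starvation-stress program** (150
   background genes, mixed-sign shifts, sd 1.0) and **resistant cells carry
   their own marker program** (100 genes, e.g. the CD52-like surface
   signature that identifies them experimentally). Without these, the
   starved subpopulations would be artificial points in expression space
   that differ from control cells only through the planted modules.

All planted programs are *interleaved across the genome* (stride-16 layout
over chromosomes 2–5). Co-expressed genes are not genomically contiguous in
real data, and placing a program on adjacent genes would masquerade as a
copy-number segment after positional smoothing. The one intentionally
contiguous structure is the planted CNV block (150 genes on chromosome 1 at
log2 dosage +1).

### Bulk multi-source design

`simulate_bulk_sources` emulates a validation design of five MDSC/control
sources: per (source, gene) Gaussian batch offsets (`source_batch_sd`,
default 0.5), residual noise (`bulk_noise_sd`, default 0.5), tolerant-module
genes shifted by their `effect_T` in **every** MDSC sample, and
sensitive-module genes shifted only in the first `n_sensitive_sources`
(default 2 of 5) sources. This is the mechanism behind the package's
central qualitative property: a signature built from genes whose induction
depends on the local stress context cannot separate MDSCs from controls in
sources where that context is absent, so its cross-source ROC AUC is
capped near `frac_active + (1 - frac_active)/2 ≈ 0.7`, while the tolerant
signature approaches 1.

## Analysis stages

- **Normalization** — log1p of counts-per-10k (natural log), the de facto
  single-cell convention. Gene z-scores use the n−1 denominator throughout
  and are clipped at ±10 before PCA to bound outlier leverage.
- **PCA** — exact truncated SVD of the centered matrix; components oriented
  so the largest-magnitude gene loading is positive.
- **Clustering** — Leiden on a shared-nearest-neighbor graph (Jaccard
  weights, prune 1/15) over 30 PCs, resolution 0.8, seeded. The defaults
  (2000 HVGs available via `select_hvgs`, 30 PCs, resolution 0.8) are
  configuration choices, not reproductions of unstated upstream settings.
- **Differential expression** — two-sided Wilcoxon rank-sum per gene
  (exact enumeration for tie-free groups of ≤10; tie- and
  continuity-corrected normal approximation otherwise; all-tied genes get
  p = 1), log2 fold change on de-logged means with ε = 1e-9, BH adjustment.
  The shared-DEG gate is padj < 0.05 and |log2fc| ≥ 0.25, exposed in config.
- **Consensus co-expression** — per-donor kNN metacells (k_agg 25, max
  shared 10, seeded greedy selection) to de-noise correlations; per-donor
  signed adjacency `((1+cor)/2)^beta` with beta chosen as the smallest
  power reaching signed scale-free fit R² ≥ 0.8 (max-R² fallback with a
  warning); topological overlap; donor TOMs scaled to a common off-diagonal
  95th percentile and combined by element-wise minimum (consensus quantile
  0). Modules come from average-linkage clustering of 1−TOM with a static
  cut at 0.995 and min size 25 — a deliberately deterministic simplification
  of the dynamic hybrid tree cut — followed by an optional kME reassignment
  pass (gap 0.1). Modules are named by size-rank color convention; the
  names will not match any particular published labeling.
- **Tolerance quadrants** — genes significant in both the cytokine contrast
  (T vs C) and the resistant contrast (resistant vs other TS) are shared
  DEGs; the sign pair assigns tolerant_up / sensitive_up / tolerant_down /
  sensitive_down. "Sensitive" requires discordant significance in both
  contrasts (the conservative reading); candidates are modules with ≥ 5
  shared DEGs and a tolerant_up majority, ranked by tolerant fraction.
- **Scoring** — signature score = mean of per-gene z-scores; the rank
  (Mann–Whitney, ties half-credit) AUC is authoritative, with a Newton
  logistic fit (gradient tolerance 1e-10, slope capped at 30 under perfect
  separation) retained as a monotone-invariance cross-check: the AUC of its
  predicted probabilities must match the rank AUC to 1e-9 whenever the
  fitted slope is positive.
- **Label transfer** — a transparent centroid classifier: z-score reference
  and query independently on shared genes (≥ 50 required), Spearman
  correlation to per-label centroids, softmax confidence. This deliberately
  replaces anchor-based transfer with something fully specified; Spearman
  makes it robust to scale differences between platforms.
- **Pre-ranked GSEA** — classic weighted (w=1) running-sum ES with a
  Monte-Carlo gene-permutation null (default 10,000 permutations; 1,000 in
  the pipeline), `p = (1 + #{|ES_null| ≥ |ES|}) / (1 + n_perm)`, NES by the
  mean same-sign null magnitude, BH across sets. Ties in the ranking
  statistic are broken by gene id for determinism. The adaptive multilevel
  p-value algorithm of the usual tool is intentionally not reproduced.
- **CNV inference** — reference-relative single pass: subtract the
  reference-cell mean per gene, clip at ±3, centered 101-gene moving
  average within each chromosome (truncated at ends, not reflected),
  per-cell median recentering, and a final re-clip so profiles stay inside
  ±clip. Subclustering is average linkage on Euclidean profile distance cut
  at k; clusters are renamed SCNV_hi…SCNV_lo by mean absolute profile
  ("burden"). A degenerate partition (burden gap < 0.02, a cluster under 5%
  of cells, or a collapsed cut) triggers a "no distinct SCNV structure"
  warning. No HMM state calling is attempted.

### Resistant-set identification inside the pipeline

The pipeline must find the resistant population without ground truth. It
classifies each starved cell against the C/T centroids on the
cytokine-responsive gene space (the significant T-vs-C DEGs), then takes a
majority vote within each Leiden cluster: clusters whose starved cells
mostly still look cytokine-treated are called resistant. This mirrors how
the original analysis pinned down its resistant cluster by per-cluster
reference enrichment, and is much more stable than per-cell calls (per-cell
accuracy ≈ 0.65 at the default conditions; cluster-vote accuracy ≈ 0.98).
If the vote is degenerate the per-cell calls are used with a warning.

## Determinism and provenance

One global seed deterministically derives per-stage seeds (CRC32 of the
stage name XOR the seed, kept below 2^31), so stages can be re-run in
isolation. Every output table carries a `# stressmod stage=...` provenance
header; the run manifest records the config hash (output location
excluded), per-stage seeds and SHA-256 checksums of all artifacts.
Re-running with an identical config reproduces identical checksums.

## Problem sizes

The packaged defaults — 2 donors × 3 groups × 500 cells, 1000 genes on 5
synthetic chromosomes, three 50-gene modules, one 150-gene CNV block, 5
bulk sources × 4 samples per arm — are the study conditions for every test
and for `scripts/acceptance.py`. They are large enough that the recovery
properties hold with margin (module Jaccard ≈ 1, CNV ARI > 0.99, transfer
accuracy > 0.95) yet small enough that the full acceptance suite runs on a
single CPU in minutes.

## What passing the tests does and does not show

The generator reproduces the *statistical structure* the analysis assumes:
NB noise, latent-factor co-expression, condition-dependent induction,
batch-offset multi-source bulk, positional dosage effects. It does not
model doublets, ambient RNA, cell-cycle effects, donor batch effects,
chromatin data, or realistic gene-length/GC biases, and synthetic
chromosomes carry evenly spaced genes (only rank order along the chromosome
matters for the smoothing step). Passing recovery tests therefore shows the
pipeline is correct and well-calibrated under its own model assumptions; it
does not certify performance on any particular real dataset. Effect sizes
are calibration choices — the magnitudes of cytokine-induced changes are
not quantified in the source material.

## Known limitations

- The static tree cut can split one planted module across two detected
  modules when the cut height is far from the default; the kME reassignment
  pass mitigates but does not eliminate this.
- The scale-free fit index is unstable for very small metacell counts;
  the max-R² fallback is then used (with a warning).
- `evaluate_module_separation` treats each contrast independently; no
  multiple-testing correction is applied across modules.
- The logistic slope cap under perfect separation is a reporting device,
  not a regularized estimate.
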