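# Methods

This note records the statistical models behind `vmsig`, the parameter
choices that matter, the design decisions taken where the procedure was
genuinely open, and what the synthetic benchmarks do and do not establish.

## Signature derivation

Derivation consumes per-gene differential-expression statistics (log₂ fold
change, p, FDR) produced upstream by DESeq2 or Limma; the package never
refits DE models. Three nested FOXC2-target sets are built:

1. **Top-up**: among genes with FDR < `alpha_sig` and log₂FC > 0, the
   `top_n` largest fold changes. `alpha_sig` defaults to 0.05 — the
   conventional significance level, stated explicitly because the source
   procedure says only "significantly". Ranking is by fold change rather
   than p-value, consistent with the fold-change-ranked lists used
   downstream; p-value ranking would be a one-line config change.
2. **Concordant**: significantly up under over-expression and significantly
   down under knockdown (signs strict, thresholds strict).
3. **Core**: concordant genes with log₂FC > 0.5 in both auxiliary
   comparisons and FDR < 10⁻⁵ with positive log₂FC in a ranking comparison,
   keeping the top `core_k = 5` by the ranking comparison's fold change.

All comparisons are strict inequalities, matching thresholds as printed
(">0.5", "<30 %", "FDR < 1 × 10⁻⁵"). Genes absent from an auxiliary table
fail that filter (conservative; counted and logged). Every ranking breaks
ties by gene identifier ascending, so derivations are deterministic.
Duplicate gene rows in a DE file keep the smallest-FDR row (then smallest
p, then first occurrence). Gene identifiers are opaque case-sensitive
strings; mouse→human conversion goes through an explicit ortholog table
(`map_orthologs`), never implicit case folding.

## Mean-Z cohort scoring

Each gene row is z-scored across samples with the sample standard
deviation (divisor n−1); zero-variance genes cannot be standardised and
are removed with a logged list. A signature's score per sample is the
arithmetic mean of its genes' z-values; genes missing from the matrix
shrink the intersection (logged) rather than erroring, unless nothing is
left. Removal of confounding samples (e.g. hematopoietic cell lines before
re-z-scoring a cell-line panel) is modelled as a generic exclusion list
applied before `zscore_genes`.

## AUC recovery-curve scoring (per cell)

For a cell with N universe genes ranked by decreasing expression, with
`m = ⌈auc_max_frac · N⌉` (the `aucMaxRank` cutoff, default 10 % of genes)
and g signature genes in the universe,

    auc = Σ_{k=1..m} H(k) / Σ_{k=1..m} min(k, g),

where H(k) counts signature genes at rank ≤ k. The perfect-recovery
denominator makes the score 1 exactly when the signature occupies the top
of the ranking and 0 when no signature gene lies within the top m. The
ceiling in m and this normalisation are fixed contracts of this package,
pinned by an independent brute-force oracle in the tests (the upstream
AUCell description leaves both unstated).

Ties — dominated by the many zero counts of sparse cells — break by gene
identifier ascending by default, giving bit-reproducible scores; a seeded
random tie mode is available to mirror AUCell's behaviour. Because the
score is purely rank-based within each cell, it is invariant under any
per-cell monotone transform: library-size normalisation does not change
it, which is also why log1p normalisation can stand in for variance-
stabilising transforms upstream of scoring (see below).

## Pre-ranked GSEA

The enrichment score is the classical weighted KS walk: with matched set S
(size N_S) on an N-gene list with metrics r,

    P_hit(i) = Σ_{j∈S, rank≤i} |r_j|^p / N_R,   N_R = Σ_{j∈S} |r_j|^p,
    P_miss(i) = #misses ≤ i / (N − N_S),

and ES is the deviation P_hit − P_miss of maximal absolute value. `p`
defaults to 1 (the cited tool's classic weighting); `p = 0` reduces to the
unweighted two-sample KS statistic, which the tests verify against an
independent KS implementation. An exact tie between equal-magnitude
positive and negative extremes resolves to the positive one; ties are
detected within a 10⁻¹² relative floating-point tolerance so rounding
cannot flip the documented rule. If all matched metrics are zero the hit
weights fall back to equal weighting (logged).

Significance uses **gene-set permutation** — the only null available to
pre-ranked input: `n_perm` (default 1000) random same-size draws from the
ranked universe, seeded. The null is computed once per distinct matched
set size within a run and shared across sets of that size (the standard
pre-ranked optimisation; results remain deterministic given the seed).
NES divides ES by the mean |null ES| of matching sign; the nominal p is
add-one corrected, `(b + 1)/(n_same_sign + 1)`, so it is never zero; the
FDR q follows the normalised-null ratio method — the fraction of pooled
same-sign null NES at least as extreme, divided by the corresponding
fraction of observed NES — clamped to [0, 1]. The signed summary is
`sign(ES) · (−log₁₀ max(q, 1/(n_perm+1)))`; the floor keeps permutation
zeros finite. Sets are size-filtered on their matched (post-intersection)
size, defaults 5–2000.

## Cohort ranking metrics

* **Correlation ranking**: the core set's per-sample mean-Z score is the
  reference variable; every gene's raw expression row is Pearson-correlated
  with it (Spearman optional). Correlating z-scored rows instead is exposed
  as an option and yields identical Pearson coefficients, z-scoring being
  linear per gene. Zero-variance genes have undefined correlation and are
  excluded with a logged count. Core genes stay in the ranked list (nothing
  in the source procedure says to remove them); `exclude_core` is provided
  for sensitivity analysis.
* **Median difference**: per gene, median over the target group minus the
  global median over all samples.
* **Mean-Z difference**: per gene, difference of group mean z-scores.

Group comparisons of signature scores use the two-sided Wilcoxon rank-sum
test: exact enumeration when both groups are small (min n ≤ 8) and the
data are tie-free, otherwise the tie- and continuity-corrected normal
approximation. Totals below 8 warn, reflecting the test's negligible power
there.

## Single-cell pipeline

QC keeps cells with 200 ≤ features ≤ 9000 (inclusive bounds) and
mitochondrial percentage strictly below 10; features must then be detected
(count > 0) in at least 5 surviving cells of **at least one** sample — the
lenient union reading of a per-sample filter applied before merging.
Filtering is idempotent and every removal is logged.

Normalisation is `ln(1 + count · 10⁴ / cell_total)`. This replaces
regression-based variance stabilisation deliberately: the downstream AUC
score is rank-based within each cell, so any per-cell monotone
normalisation gives identical scores, and marker fold changes operate on
linearised means where the choice enters only through the pseudocount.

Tumor clusters are those with strictly more than 20 % CellTag-positive
cells. The endo-high population is the top `⌈0.05 · n⌉` AUC scores within
a selection universe (all tumor cells by default; the `within` argument
supports per-sample or per-treatment selection). Marker ranking compares
endo-high to the rest: log₂((mean_hi + ε)/(mean_rest + ε)) on linearised
(expm1) values with rate pseudocount ε = 1/norm_scale = 10⁻⁴ by default,
rank-sum p per gene and BH q; no min-pct or min-lfc prefilter is applied
by default so the ranked list covers the full gene universe for GSEA
(prefilters are options). Pseudo-bulk sums a cluster's counts per gene per
sample and conserves totals exactly.

## Synthetic data

All generators are pure functions of spec + seed and ship ground-truth
sidecars.

* **DE quartet** (2000 genes): 5 core genes pass every derivation filter
  with margin (over-expression log₂FC ∈ [1.5, 4], knockdown negated,
  auxiliary log₂FC ∈ [1, 2.5], ranking log₂FC ∈ [3, 4] with p ≈ 10⁻¹¹);
  45 concordant decoys each fail exactly one downstream filter, cycling
  deterministically through the three failure modes; the rest are null
  (uniform p, |log₂FC| < 0.3). FDR columns are BH-computed within each
  table from these p-values, so null genes can occasionally reach nominal
  significance in one table, as in real data; core recovery is unaffected
  by construction.
* **Cohort** (3000 genes × 500 samples): module genes follow
  `0.8·f + √(1−0.8²)·ε` with a standard-normal latent factor f per sample,
  giving pairwise module correlation 0.8² = 0.64 *within subtype*; a 1-SD
  shift on module genes in the balanced "aggressive" subtype adds
  between-group signal. The calibration test centres within subtype before
  measuring module correlation, since the shift itself contributes
  covariance across groups.
* **Single cell** (2000 genes; 1500 tumor / 300 endothelial / 300
  fibroblast cells plus planted QC violators): counts are negative
  binomial with per-gene log-normal base means (median ≈ 1 count, a
  desk-scale stand-in for shallow droplet data) and dispersion 0.5
  (variance μ + 0.5 μ²; dispersion is the inverse of the NB size
  parameter). The 100 endothelial-signature genes are elevated 4-fold in
  endothelial cells **and** in the 5 % endothelial-like tumor fraction —
  ectopic endothelial expression, the premise of the VM phenotype — while
  a disjoint 50-gene FOXC2-program set is elevated in the endo-like tumor
  cells only, giving the marker-GSEA stage planted signal. Ten `mt-`
  genes define the mitochondrial percentage exactly; a CellTag barcode
  gene is detected in 60 % of tumor-lineage cells. QC violators are
  planted orthogonally, one rule each (100-feature cells for the low
  bound, ~33 % mitochondrial cells for the mito rule), so the filter
  report is exactly predictable. At 2000 genes the high-feature rule
  (> 9000) cannot be violated; requesting such a violator without enough
  genes raises.

## Problem sizes and numerical choices

The benchmark sizes are chosen so the whole suite runs in minutes on one
CPU while every statistical claim still has power: 200 random instances
for the AUC oracle (universes ≤ 50 genes), exhaustive subsets of lists up
to length 8 for the ES oracle, 200 random 20-gene sets on a 1000-gene
list at 1000 permutations for null calibration, and 1000 simulations each
for rank-sum uniformity and power (1000 rather than a nominal 100 for the
power estimate, keeping its Monte-Carlo standard error near 0.6 %).
RNK files are written with shortest round-trip float representation so
write→read is the identity. The rank-sum power check (1-SD shift, 30 vs
30) sits near its 0.95 bound because the true power of the test at that
effect size is ≈ 0.957.

## Limitations

Passing the synthetic benchmarks shows the machinery is implemented
correctly and recovers planted structure under the stated generative
models; it does not establish performance on real data, where ambient RNA,
doublets, batch effects, correlated DE statistics and non-NB dispersion
all exist and are deliberately not emulated. The GSEA null is gene-set
permutation only (phenotype permutation does not apply to pre-ranked
input), which is known to be anti-conservative when genes are strongly
correlated. Cluster labels, DE statistics and nucleus category counts are
inputs, not outputs: clustering, integration, DE model fitting and image
segmentation are out of scope.
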