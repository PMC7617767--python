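# vmsig

Gene-signature machinery for studying **vasculogenic mimicry (VM)** — the
formation of perfused, matrix-lined pseudo-vessels by tumor cells that lack
endothelial identity — and its transcriptional driver **FOXC2**. The package
is aimed at computational biologists who need to derive target-gene
signatures from differential-expression output, score those signatures in
bulk cohorts and in single cells, and test them for enrichment with a fully
reproducible, self-contained toolchain.

## What it implements

* **Signature derivation** (`vmsig.signatures`) — nested FOXC2-target gene
  sets from DE tables: the top-100 significantly up-regulated genes by
  log₂FC; the *concordant* set (significantly up under over-expression ∧
  significantly down under knockdown); and the high-confidence *core* set
  (concordant ∧ log₂FC > 0.5 in two auxiliary comparisons ∧ FDR < 10⁻⁵ in a
  ranking comparison, top 5 by that comparison's log₂FC). Endothelial sets
  are refined by set subtraction and by endothelial-vs-fibroblast cluster
  statistics (log₂FC > 0.5, detected in < 30 % of fibroblasts).
* **Signature scoring** (`vmsig.scoring`) — per-sample mean-Z scores
  (z-score each gene across samples, average over the signature); per-cell
  AUC recovery-curve scores with an `aucMaxRank` cutoff of 10 % of genes
  (AUCell-style, rank-based and normalisation-invariant); and the
  immunofluorescence H-score `100·(1·%weak + 2·%moderate + 3·%strong)`.
* **Pre-ranked GSEA** (`vmsig.gsea`) — a from-scratch weighted
  Kolmogorov–Smirnov enrichment score

  `ES = max-deviation of  P_hit(i) − P_miss(i)`, `P_hit(i) = Σ_{j∈S, rank≤i} |r_j|^p / N_R`,

  with gene-set-permutation null, NES, add-one nominal p, normalised-null
  FDR q, leading edges and the signed −log₁₀(q) summary.
* **Cohort metrics** (`vmsig.cohort`) — correlation of every gene with a
  core signature's mean-Z score (the ranking metric for clinical cohorts),
  median-difference and mean-Z-difference metrics for cell-line panels,
  plus two-sided Wilcoxon rank-sum group comparisons.
* **Single-cell pipeline** (`vmsig.endo_pipeline`) — QC (200–9000 features,
  < 10 % mitochondrial reads, features in ≥ 5 cells of a sample), log1p
  library normalisation, CellTag > 20 % tumor-cluster calls, top-5 %
  *endo-high* classification, marker ranking (linearised log₂FC, rank-sum
  p, BH q) and per-sample pseudo-bulk aggregation.
* **Synthetic data** (`vmsig.synthetic_data`) — seeded generators for DE
  quartets with planted core genes, cohort matrices with a planted
  latent-factor module, and negative-binomial single-cell counts with a
  planted endothelial-like tumor subpopulation, each with ground-truth
  sidecars.

## Worked example

Recover a planted endothelial-like tumor subpopulation from synthetic
single-cell counts:

```python
from vmsig import *
from vmsig.synthetic_data import gen_sc_dataset, ScSpec
from vmsig.endo_pipeline import ScConfig

ds = gen_sc_dataset(ScSpec(seed=0))            # 2106 cells x 2000 genes
cfg = ScConfig()
counts, ann = qc_filter(ds.counts, ds.annotation, cfg)
calls = classify_tumor_clusters(ann, cfg)      # CellTag > 20% rule
tumor = [c for c, cl in zip(ann.data.cell, ann.data.cluster)
         if calls[str(cl)] == "tumor"]
scores = aucell_score(counts, ds.endothelial_set, auc_max_frac=0.10)
labels, thr = classify_endo_high(scores, cfg, within=tumor)

hit = {c for c, v in labels.items() if v == "endo_high"}
truth = set(ds.cell_types.index[ds.cell_types == "endo_like_tumor"])
print(len(hit), len(truth), len(hit & truth), round(thr, 3))
```

prints

```
75 75 75 0.277
```

— the top 5 % of 1500 tumor cells (75 cells, AUC threshold 0.277) are
exactly the 75 planted endothelial-like tumor cells: precision and recall
are both 1.0 on this seed. Running GSEA on the endo-high marker ranking
(`rank_markers` → `gsea_preranked`) flags the planted FOXC2-program set
with a strongly positive enrichment score and FDR q below 0.001.

The same workflows are available from the shell:

```bash
vmsig simulate sc --seed 0 --out-dir sim/
vmsig sc run --mtx sim/matrix.mtx --genes sim/matrix.genes.txt \
    --cells sim/matrix.cells.txt --ann sim/ann.tsv \
    --endo-set sim/truth/sets.gmt:planted_endothelial --out-dir results/
vmsig gsea --rnk results/markers.rnk --gmt sim/truth/sets.gmt \
    --n-perm 1000 --seed 7 --out results/gsea.tsv
```

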