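"""Seeded generators for DE-table quartets, cohort matrices and single-cell
count data with planted signals.

Each generator is a pure function of its spec (including the seed): the same
spec yields byte-identical output.  Ground-truth sidecars record every
planted structure so downstream recovery (signature derivation, endo-high
classification, enrichment ranking) can be measured as precision/recall
without re-deriving the simulation.

What the generators emulate and what they do not: the DE quartet reproduces
the *filter geometry* of a concordant-plus-auxiliary derivation (planted
core genes pass every filter with margin, decoys fail exactly one), not the
correlation structure of real DE statistics; the cohort generator plants a
single latent-factor gene module, not the full covariance of tumor
transcriptomes; the single-cell generator draws independent
negative-binomial counts per gene and cell (no ambient RNA, doublets or
batch effects) at desk scale rather than the depth of a real 10x run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse

from vmsig.endo_pipeline import CellAnnotation
from vmsig.io_formats import CountMatrix, DEResultTable, ExpressionMatrix, GeneSet
from vmsig.gsea import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "DeQuartetSpec",
    "CohortSpec",
    "ScSpec",
    "DeQuartet",
    "CohortData",
    "ScDataset",
    "gen_de_quartet",
    "gen_cohort",
    "gen_sc_dataset",
]


# ---------------------------------------------------------------------------
# DE quartet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeQuartetSpec:
    """Spec for four DE tables with planted concordant/core target genes.

    ``n_core`` genes pass every derivation filter with margin;
    ``n_concordant_extra`` genes pass the concordance step but fail exactly
    one auxiliary/ranking filter; the rest are null (uniform p, fold
    changes within ``+-lfc_decoy``).  FDRs are Benjamini-Hochberg within
    each table.
    """

    n_genes: int = 2000
    n_core: int = 5
    n_concordant_extra: int = 45
    lfc_core: float = 3.0
    lfc_decoy: float = 0.3
    fdr_core: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_core + self.n_concordant_extra >= self.n_genes:
            raise ValueError("planted genes must be fewer than n_genes")
        if not (self.lfc_core > 0.5 > self.lfc_decoy):
            raise ValueError("require lfc_core > 0.5 > lfc_decoy")
        if self.n_core < 0 or self.n_concordant_extra < 0:
            raise ValueError("planted counts must be non-negative")


class DeQuartet(NamedTuple):
    """Four DE tables plus the ground-truth sidecar (gene, role)."""

    oe_up: DEResultTable       # over-expression comparison (planted genes up)
    kd_down: DEResultTable     # knockdown comparison (planted genes down)
    aux1: DEResultTable        # first auxiliary comparison
    aux2: DEResultTable        # second auxiliary, doubles as ranking table
    truth: pd.DataFrame        # columns: gene, role in {core, concordant_extra, null}

    @property
    def core_genes(self) -> frozenset[str]:
        return frozenset(self.truth.loc[self.truth["role"] == "core", "gene"])

    @property
    def concordant_genes(self) -> frozenset[str]:
        return frozenset(
            self.truth.loc[self.truth["role"].isin(["core", "concordant_extra"]), "gene"]
        )


def _de_table(name: str, genes: np.ndarray, lfc: np.ndarray, p: np.ndarray) -> DEResultTable:
    fdr = np.asarray(bh_fdr(list(p)))
    return DEResultTable(
        name, pd.DataFrame({"gene": genes, "log2fc": lfc, "pvalue": p, "fdr": fdr})
    )


def gen_de_quartet(spec: DeQuartetSpec = DeQuartetSpec()) -> DeQuartet:
    """Generate the four DE tables behind core-signature derivation.

    Planted core genes are significantly up in the over-expression table,
    significantly down in the knockdown table, above the 0.5 log2FC margin
    in both auxiliary comparisons and carry the largest fold changes with
    tiny FDR in the ranking comparison.  Each concordant decoy fails exactly
    one of the three downstream filters (cycled deterministically).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_genes
    genes = np.array([f"G{i:05d}" for i in range(n)])
    planted = rng.choice(n, size=spec.n_core + spec.n_concordant_extra, replace=False)
    core_idx = planted[: spec.n_core]
    extra_idx = planted[spec.n_core:]
    roles = np.full(n, "null", dtype=object)
    roles[core_idx] = "core"
    roles[extra_idx] = "concordant_extra"

    tiny = spec.fdr_core * 1e-3

    def null_lfc(size: int) -> np.ndarray:
        return rng.uniform(-spec.lfc_decoy, spec.lfc_decoy, size=size)

    def base_table() -> tuple[np.ndarray, np.ndarray]:
        return null_lfc(n), rng.uniform(0, 1, size=n)

    # over-expression: planted strongly up
    lfc, p = base_table()
    lfc[planted] = rng.uniform(1.5, spec.lfc_core + 1.0, size=len(planted))
    p[planted] = tiny * rng.uniform(0.1, 1.0, size=len(planted))
    oe = _de_table("foxc2_oe_up", genes, lfc, p)

    # knockdown: planted strongly down
    lfc, p = base_table()
    lfc[planted] = -rng.uniform(1.5, spec.lfc_core + 1.0, size=len(planted))
    p[planted] = tiny * rng.uniform(0.1, 1.0, size=len(planted))
    kd = _de_table("foxc2_kd_down", genes, lfc, p)

    # decoy failure modes: 0 fail aux1 lfc, 1 fail aux2 lfc, 2 fail aux2 fdr
    modes = np.arange(len(extra_idx)) % 3

    # aux1: core pass with margin; mode-0 decoys fail
    lfc, p = base_table()
    lfc[core_idx] = rng.uniform(1.0, 2.5, size=len(core_idx))
    p[core_idx] = tiny * rng.uniform(0.1, 1.0, size=len(core_idx))
    pass1 = extra_idx[modes != 0]
    fail1 = extra_idx[modes == 0]
    lfc[pass1] = rng.uniform(1.0, 2.5, size=len(pass1))
    lfc[fail1] = rng.uniform(-0.3, 0.4, size=len(fail1))
    p[extra_idx] = tiny * rng.uniform(0.1, 1.0, size=len(extra_idx))
    aux1 = _de_table("lung_vs_primary", genes, lfc, p)

    # aux2 / ranking table: core carry the largest lfc and tiny fdr
    lfc, p = base_table()
    lfc[core_idx] = spec.lfc_core + rng.uniform(0.0, 1.0, size=len(core_idx))
    p[core_idx] = tiny * rng.uniform(0.1, 1.0, size=len(core_idx))
    pass2 = extra_idx[modes == 0]          # fail aux1 instead; pass here
    fail_lfc = extra_idx[modes == 1]       # small positive lfc, below margin
    fail_fdr = extra_idx[modes == 2]       # good lfc but non-significant
    lfc[pass2] = rng.uniform(1.0, 2.5, size=len(pass2))
    p[pass2] = tiny * rng.uniform(0.1, 1.0, size=len(pass2))
    lfc[fail_lfc] = rng.uniform(0.05, 0.4, size=len(fail_lfc))
    p[fail_lfc] = tiny * rng.uniform(0.1, 1.0, size=len(fail_lfc))
    lfc[fail_fdr] = rng.uniform(1.0, 2.5, size=len(fail_fdr))
    p[fail_fdr] = rng.uniform(0.3, 1.0, size=len(fail_fdr))
    aux2 = _de_table("vm_vs_all", genes, lfc, p)

    truth = pd.DataFrame({"gene": genes, "role": roles})
    return DeQuartet(oe_up=oe, kd_down=kd, aux1=aux1, aux2=aux2, truth=truth)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Spec for a cohort matrix with a planted correlated gene module.

    Module genes follow ``loading * f_s + sqrt(1 - loading^2) * noise`` for
    a standard-normal latent factor ``f`` per sample, giving pairwise module
    correlation ``loading^2`` (within subtype); non-module genes are pure
    standard normal noise.  Module genes are additionally shifted by
    ``subtype_shift`` SD in the *aggressive* subtype.
    """

    n_samples: int = 500
    n_genes: int = 3000
    n_module_genes: int = 50
    n_core_genes: int = 5
    module_loading: float = 0.8
    subtype_shift: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_module_genes >= self.n_genes:
            raise ValueError("n_module_genes must be < n_genes")
        if not (0 < self.module_loading < 1):
            raise ValueError("module_loading must lie in (0, 1)")
        if not (0 < self.n_core_genes <= self.n_module_genes):
            raise ValueError("n_core_genes must lie in (0, n_module_genes]")


class CohortData(NamedTuple):
    """Cohort matrix, subtype labels and planted gene sets."""

    matrix: ExpressionMatrix
    groups: pd.Series                  # sample -> subtype label
    module_set: GeneSet                # the planted correlated module
    core_set: GeneSet                  # small core subset used for scoring


def gen_cohort(spec: CohortSpec = CohortSpec()) -> CohortData:
    """Generate a cohort expression matrix with one planted gene module."""
    rng = np.random.default_rng(spec.seed)
    genes = np.array([f"C{i:05d}" for i in range(spec.n_genes)])
    samples = np.array([f"P{i:04d}" for i in range(spec.n_samples)])
    module_idx = rng.choice(spec.n_genes, size=spec.n_module_genes, replace=False)
    core_idx = module_idx[: spec.n_core_genes]

    factor = rng.standard_normal(spec.n_samples)
    x = rng.standard_normal((spec.n_genes, spec.n_samples))
    lam = spec.module_loading
    x[module_idx] = lam * factor + np.sqrt(1 - lam**2) * x[module_idx]

    labels = np.array(["aggressive", "other"])[np.arange(spec.n_samples) % 2]
    labels = labels[rng.permutation(spec.n_samples)]
    x[np.ix_(module_idx, np.flatnonzero(labels == "aggressive"))] += spec.subtype_shift

    matrix = ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=samples), value_scale="linear"
    )
    groups = pd.Series(labels, index=samples)
    module_set = GeneSet("planted_module", frozenset(genes[module_idx]),
                         "latent-factor correlated module")
    core_set = GeneSet("planted_core", frozenset(genes[core_idx]),
                       "core subset of the planted module")
    return CohortData(matrix=matrix, groups=groups, module_set=module_set, core_set=core_set)


# ---------------------------------------------------------------------------
# Single-cell dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScSpec:
    """Spec for a single-cell count matrix with a planted endothelial-like
    tumor subpopulation.

    Counts are negative binomial with per-gene base means (log-normal) and a
    common dispersion (``dispersion = 1/size``; variance ``mu + dispersion *
    mu^2``).  Endothelial-signature genes are elevated ``endo_fold``-fold in
    endothelial cells *and* in the planted endothelial-like tumor fraction
    (ectopic endothelial expression); a disjoint FOXC2-program set is
    elevated in the endo-like tumor cells only, so marker-based enrichment
    has planted signal.  A CellTag barcode gene is expressed in tumor cells
    with the stated detection probability.  QC violators are planted
    orthogonally, each failing exactly one filter rule.
    """

    n_genes: int = 2000
    n_tumor: int = 1500
    n_endothelial: int = 300
    n_fibroblast: int = 300
    endo_like_tumor_frac: float = 0.05
    endothelial_signature_size: int = 100
    foxc2_program_size: int = 50
    endo_fold: float = 4.0
    dispersion: float = 0.5
    base_mean_log_mu: float = 0.0
    base_mean_log_sd: float = 0.7
    n_mito_genes: int = 10
    celltag_detection: float = 0.6
    n_samples: int = 2
    n_qc_low_feature: int = 3
    n_qc_high_mito: int = 3
    n_qc_high_feature: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.endo_like_tumor_frac < 1):
            raise ValueError("endo_like_tumor_frac must lie in (0, 1)")
        if not (0 < self.celltag_detection < 1):
            raise ValueError("celltag_detection must lie in (0, 1)")
        for name in ("n_genes", "n_tumor", "n_endothelial", "n_fibroblast",
                     "endo_fold", "dispersion", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        reserved = self.endothelial_signature_size + self.foxc2_program_size + self.n_mito_genes
        if reserved >= self.n_genes:
            raise ValueError("signature + program + mito genes must be < n_genes")


class ScDataset(NamedTuple):
    """Counts, annotation and ground truth of a synthetic single-cell run."""

    counts: CountMatrix
    annotation: CellAnnotation
    cell_types: pd.Series              # cell -> ground-truth type
    endothelial_set: GeneSet
    foxc2_program_set: GeneSet
    qc_violators: list[str]            # cells planted to fail exactly one QC rule


def gen_sc_dataset(spec: ScSpec = ScSpec()) -> ScDataset:
    """Generate a synthetic single-cell dataset with planted populations."""
    if spec.n_qc_high_feature > 0 and spec.n_genes <= 9000:
        raise ValueError(
            "planting a high-feature QC violator requires n_genes above the "
            "max_features threshold"
        )
    rng = np.random.default_rng(spec.seed)
    size = 1.0 / spec.dispersion  # NB size parameter

    # --- genes: neutral ids with roles at random positions; mito/celltag named
    n_named = spec.n_genes - spec.n_mito_genes - 1
    gene_ids = np.array([f"G{i:05d}" for i in range(n_named)]
                        + [f"mt-{i + 1}" for i in range(spec.n_mito_genes)]
                        + ["CellTag-V1"])
    mito_idx = np.arange(n_named, n_named + spec.n_mito_genes)
    celltag_idx = spec.n_genes - 1
    special = rng.choice(
        n_named, size=spec.endothelial_signature_size + spec.foxc2_program_size,
        replace=False,
    )
    endo_idx = special[: spec.endothelial_signature_size]
    foxc2_idx = special[spec.endothelial_signature_size:]

    base_mean = rng.lognormal(spec.base_mean_log_mu, spec.base_mean_log_sd, spec.n_genes)
    base_mean[celltag_idx] = 0.0  # handled separately

    # --- cells
    n_endo_like = int(round(spec.endo_like_tumor_frac * spec.n_tumor))
    groups = (
        ["tumor"] * (spec.n_tumor - n_endo_like)
        + ["endo_like_tumor"] * n_endo_like
        + ["endothelial"] * spec.n_endothelial
        + ["fibroblast"] * spec.n_fibroblast
        + ["qc_low_feature"] * spec.n_qc_low_feature
        + ["qc_high_mito"] * spec.n_qc_high_mito
        + ["qc_high_feature"] * spec.n_qc_high_feature
    )
    cell_type = np.array(groups, dtype=object)
    n_cells = len(cell_type)
    order = rng.permutation(n_cells)
    cell_type = cell_type[order]
    cell_ids = np.array([f"CELL{i:05d}" for i in range(n_cells)])

    # --- per-cell mean profiles
    mu = np.tile(base_mean[:, None], (1, n_cells)).astype(float)
    is_tumorlike = np.isin(cell_type, ["tumor", "endo_like_tumor",
                                       "qc_low_feature", "qc_high_mito", "qc_high_feature"])
    is_endo_cell = cell_type == "endothelial"
    is_endo_like = cell_type == "endo_like_tumor"
    mu[np.ix_(endo_idx, np.flatnonzero(is_endo_cell | is_endo_like))] *= spec.endo_fold
    mu[np.ix_(foxc2_idx, np.flatnonzero(is_endo_like))] *= spec.endo_fold

    p_nb = size / (size + mu)
    counts = rng.negative_binomial(size, p_nb).astype(np.int64)

    # CellTag: expressed in tumor-lineage cells with the stated detection rate
    tag = np.zeros(n_cells, dtype=np.int64)
    tcols = np.flatnonzero(is_tumorlike)
    detected = rng.random(len(tcols)) < spec.celltag_detection
    tag[tcols[detected]] = 1 + rng.poisson(1.0, int(detected.sum()))
    counts[celltag_idx] = tag

    # --- planted QC violators (each fails exactly one rule)
    for col in np.flatnonzero(cell_type == "qc_low_feature"):
        keep = rng.choice(n_named, size=100, replace=False)  # 100 features < min 200
        new = np.zeros(spec.n_genes, dtype=np.int64)
        new[keep] = 1 + rng.poisson(1.0, len(keep))
        counts[:, col] = new  # no mito counts -> passes the mito rule
    for col in np.flatnonzero(cell_type == "qc_high_mito"):
        non_mito_total = counts[:, col].sum() - counts[mito_idx, col].sum()
        per_gene = max(1, int(np.ceil(0.5 * non_mito_total / spec.n_mito_genes)))
        counts[mito_idx, col] = per_gene  # mito fraction ~= 33% > 10%
    # (high-feature violators would need n_genes > 9000; guarded above)

    # --- annotation computed exactly from the counts
    totals = counts.sum(axis=0)
    mito_pct = 100.0 * counts[mito_idx].sum(axis=0) / totals
    n_features = (counts > 0).sum(axis=0)
    samples = np.array([f"S{1 + i % spec.n_samples}" for i in range(n_cells)])
    samples = samples[rng.permutation(n_cells)]
    cluster = np.where(
        is_tumorlike,
        np.where(rng.random(n_cells) < 0.5, "tumor_1", "tumor_2"),
        np.where(is_endo_cell, "endothelial", "fibroblast"),
    )
    ann = CellAnnotation(pd.DataFrame({
        "cell": cell_ids,
        "sample": samples,
        "cluster": cluster,
        "n_features": n_features,
        "mito_pct": mito_pct,
        "celltag_positive": counts[celltag_idx] > 0,
    }))

    cm = CountMatrix(scipy.sparse.csr_matrix(counts), gene_ids, cell_ids)
    violators = list(cell_ids[np.isin(cell_type, ["qc_low_feature", "qc_high_mito",
                                                  "qc_high_feature"])])
    return ScDataset(
        counts=cm,
        annotation=ann,
        cell_types=pd.Series(cell_type, index=cell_ids),
        endothelial_set=GeneSet("planted_endothelial", frozenset(gene_ids[endo_idx]),
                                "elevated in endothelial and endo-like tumor cells"),
        foxc2_program_set=GeneSet("planted_foxc2_program", frozenset(gene_ids[foxc2_idx]),
                                  "co-elevated in endo-like tumor cells"),
        qc_violators=violators,
    )
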