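"""Derivation of FOXC2-target and endothelial gene sets from DE tables.

The derivation pipeline mirrors the construction of three nested
FOXC2-target gene sets from over-expression / knockdown differential
expression:

* *top-up* — the top ``top_n`` FDR-significant up-regulated genes of one
  comparison, ranked by log2 fold change;
* *concordant* — genes significantly up in the over-expression comparison
  and significantly down in the knockdown comparison;
* *core* — concordant genes additionally showing log2FC above a margin in
  two auxiliary comparisons and very strong up-regulation
  (FDR < ``core_fdr_max``) in a ranking comparison, keeping the top
  ``core_k`` by that ranking comparison's fold change.

Endothelial sets are refined by set subtraction (removing mesenchymal
genes) and by single-cell cluster statistics (endothelial-vs-fibroblast
fold change and fibroblast detection percentage).

All threshold comparisons are strict, matching the source thresholds as
printed (">0.5", "<30%", "FDR < 1e-5"); ranking ties break by gene
identifier ascending so every derivation is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from vmsig.io_formats import DEResultTable, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "EmptyGeneSetError",
    "DerivationConfig",
    "ClusterExpressionStats",
    "derive_top_up",
    "derive_concordant",
    "derive_core",
    "subtract_gene_set",
    "refine_by_cluster_stats",
    "map_orthologs",
]


class EmptyGeneSetError(ValueError):
    """A derivation step produced no genes."""


@dataclass(frozen=True)
class DerivationConfig:
    """Thresholds controlling gene-set derivation.

    Parameters
    ----------
    top_n
        Size of the top-up set (default 100).
    alpha_sig
        FDR threshold defining "significant" (default 0.05).
    aux_lfc_min
        Strict log2FC lower bound in the auxiliary comparisons (default 0.5).
    core_fdr_max
        Strict FDR upper bound in the ranking comparison (default 1e-5).
    core_k
        Number of core genes retained (default 5).
    """

    top_n: int = 100
    alpha_sig: float = 0.05
    aux_lfc_min: float = 0.5
    core_fdr_max: float = 1e-5
    core_k: int = 5

    def __post_init__(self) -> None:
        if not (0 < self.alpha_sig < 1):
            raise ValueError("alpha_sig must lie in (0, 1)")
        if not (0 < self.core_fdr_max < 1):
            raise ValueError("core_fdr_max must lie in (0, 1)")
        if self.core_k < 1:
            raise ValueError("core_k must be >= 1")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")


class ClusterExpressionStats:
    """Per-gene target-vs-background cluster statistics.

    Columns: ``gene``, ``log2fc_target_vs_background`` and
    ``pct_expressed_background`` (percent of background-cluster cells
    detecting the gene, in [0, 100]).
    """

    COLUMNS = ("gene", "log2fc_target_vs_background", "pct_expressed_background")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"cluster stats missing columns {missing}")
        df = data.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        df["gene"] = df["gene"].astype(str)
        if df["gene"].duplicated().any():
            raise ValueError("duplicate genes in cluster stats")
        pct = df["pct_expressed_background"].to_numpy(dtype=float)
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("pct_expressed_background must lie in [0, 100]")
        self.data = df

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("gene")


def _sig_up(de: DEResultTable, alpha: float) -> pd.DataFrame:
    df = de.data
    return df[(df["fdr"] < alpha) & (df["log2fc"] > 0)]


def _sig_down(de: DEResultTable, alpha: float) -> pd.DataFrame:
    df = de.data
    return df[(df["fdr"] < alpha) & (df["log2fc"] < 0)]


def derive_top_up(
    de: DEResultTable, cfg: DerivationConfig = DerivationConfig(), name: str | None = None
) -> GeneSet:
    """Top ``cfg.top_n`` significantly up-regulated genes, by log2FC.

    Among genes with ``fdr < alpha_sig`` and ``log2fc > 0``, take the
    ``top_n`` largest fold changes (ties by gene identifier ascending).  If
    fewer qualify, all are returned with a warning.
    """
    if len(de) == 0:
        raise ValueError("DE table is empty")
    qual = _sig_up(de, cfg.alpha_sig)
    if qual.empty:
        raise EmptyGeneSetError(
            f"no genes with fdr < {cfg.alpha_sig} and log2fc > 0 in {de.comparison_name!r}"
        )
    ordered = qual.sort_values(
        ["log2fc", "gene"], ascending=[False, True], kind="stable"
    )
    if len(ordered) < cfg.top_n:
        logger.warning(
            "%s: only %d genes qualify for top %d up-regulated",
            de.comparison_name, len(ordered), cfg.top_n,
        )
    top = ordered.head(cfg.top_n)
    return GeneSet(
        name=name or f"{de.comparison_name}_top{cfg.top_n}_up",
        description=f"top {cfg.top_n} up-regulated (fdr<{cfg.alpha_sig}) by log2fc",
        members=frozenset(top["gene"]),
    )


def derive_concordant(
    de_up: DEResultTable,
    de_down: DEResultTable,
    cfg: DerivationConfig = DerivationConfig(),
    name: str = "concordant",
) -> GeneSet:
    """Genes significantly up in ``de_up`` and significantly down in ``de_down``."""
    if len(de_up) == 0 or len(de_down) == 0:
        raise ValueError("DE tables must be non-empty")
    up = set(_sig_up(de_up, cfg.alpha_sig)["gene"])
    down = set(_sig_down(de_down, cfg.alpha_sig)["gene"])
    members = up & down
    if not members:
        raise EmptyGeneSetError(
            f"no concordant genes between {de_up.comparison_name!r} "
            f"and {de_down.comparison_name!r}"
        )
    return GeneSet(
        name=name,
        description=(
            f"up in {de_up.comparison_name} and down in {de_down.comparison_name} "
            f"(fdr<{cfg.alpha_sig})"
        ),
        members=frozenset(members),
    )


def derive_core(
    concordant: GeneSet,
    aux1: DEResultTable,
    aux2: DEResultTable,
    rank_table: DEResultTable,
    cfg: DerivationConfig = DerivationConfig(),
    name: str = "core",
) -> GeneSet:
    """High-confidence core genes from a concordant set.

    Keeps concordant genes with ``log2fc > aux_lfc_min`` in *both* auxiliary
    comparisons and ``fdr < core_fdr_max`` with ``log2fc > 0`` in the
    ranking comparison, then returns the top ``core_k`` by the ranking
    comparison's log2FC (ties by gene identifier).  Genes absent from any
    table fail that filter (logged).  Fewer than ``core_k`` survivors is a
    warning, zero survivors an error.
    """
    for t in (aux1, aux2, rank_table):
        if len(t) == 0:
            raise ValueError("auxiliary / ranking tables must be non-empty")

    genes = sorted(concordant.members)
    a1 = aux1.indexed()
    a2 = aux2.indexed()
    rk = rank_table.indexed()

    n_missing = sum(1 for g in genes if g not in a1.index or g not in a2.index or g not in rk.index)
    if n_missing:
        logger.warning(
            "derive_core: %d concordant genes absent from an auxiliary/ranking table "
            "(treated as failing)", n_missing,
        )

    survivors: list[tuple[str, float]] = []
    for g in genes:
        if g not in a1.index or g not in a2.index or g not in rk.index:
            continue
        if not (a1.at[g, "log2fc"] > cfg.aux_lfc_min and a2.at[g, "log2fc"] > cfg.aux_lfc_min):
            continue
        if not (rk.at[g, "fdr"] < cfg.core_fdr_max and rk.at[g, "log2fc"] > 0):
            continue
        survivors.append((g, float(rk.at[g, "log2fc"])))

    if not survivors:
        raise EmptyGeneSetError("no concordant gene survives the core filters")
    if len(survivors) < cfg.core_k:
        logger.warning(
            "derive_core: only %d survivors for core_k=%d", len(survivors), cfg.core_k
        )
    survivors.sort(key=lambda t: (-t[1], t[0]))
    members = frozenset(g for g, _ in survivors[: cfg.core_k])
    return GeneSet(
        name=name,
        description=(
            f"top {cfg.core_k} of {len(survivors)} survivors by {rank_table.comparison_name} "
            f"log2fc (aux lfc>{cfg.aux_lfc_min}, fdr<{cfg.core_fdr_max})"
        ),
        members=members,
    )


def subtract_gene_set(base: GeneSet, removed: GeneSet | frozenset[str], new_name: str) -> GeneSet:
    """Set difference ``base \\ removed`` under a new name."""
    removed_members = removed.members if isinstance(removed, GeneSet) else frozenset(removed)
    members = base.members - removed_members
    if not members:
        raise EmptyGeneSetError(f"subtracting left {base.name!r} empty")
    return GeneSet(name=new_name, description=f"{base.name} minus {len(removed_members)} genes",
                   members=members)


def refine_by_cluster_stats(
    base: GeneSet,
    stats: ClusterExpressionStats,
    lfc_min: float = 0.5,
    pct_max: float = 30.0,
    new_name: str | None = None,
) -> GeneSet:
    """Keep genes enriched in the target cluster and rare in the background.

    A gene survives iff its target-vs-background log2FC is strictly above
    ``lfc_min`` and the percentage of background cells expressing it is
    strictly below ``pct_max``.  Genes of ``base`` absent from ``stats`` are
    dropped with a logged count.
    """
    st = stats.indexed()
    present = [g for g in sorted(base.members) if g in st.index]
    if not present:
        raise ValueError("cluster stats cover no gene of the base set")
    n_absent = len(base.members) - len(present)
    if n_absent:
        logger.warning("refine_by_cluster_stats: %d genes of %r absent from stats (dropped)",
                       n_absent, base.name)
    kept = [
        g for g in present
        if st.at[g, "log2fc_target_vs_background"] > lfc_min
        and st.at[g, "pct_expressed_background"] < pct_max
    ]
    if not kept:
        raise EmptyGeneSetError("no gene survives the cluster-statistics refinement")
    return GeneSet(
        name=new_name or f"{base.name}_refined",
        description=f"{base.name} with lfc>{lfc_min} and background pct<{pct_max}",
        members=frozenset(kept),
    )


def map_orthologs(
    set_in: GeneSet,
    ortholog_table: Mapping[str, str | Sequence[str]],
    new_name: str | None = None,
) -> GeneSet:
    """Map members through an ortholog table (e.g. mouse symbol -> human).

    Each source may map to one or several targets; unmapped members are
    counted and logged; duplicate targets collapse.
    """
    targets: set[str] = set()
    n_unmapped = 0
    for g in sorted(set_in.members):
        if g not in ortholog_table:
            n_unmapped += 1
            continue
        t = ortholog_table[g]
        if isinstance(t, str):
            targets.add(t)
        else:
            targets.update(t)
    if n_unmapped:
        logger.warning("map_orthologs: %d of %d members unmapped", n_unmapped, len(set_in))
    if not targets:
        raise EmptyGeneSetError(f"no member of {set_in.name!r} could be mapped")
    return GeneSet(
        name=new_name or f"{set_in.name}_mapped",
        description=f"{set_in.name} mapped through ortholog table",
        members=frozenset(targets),
    )
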