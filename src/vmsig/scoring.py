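"""Signature scoring: cohort mean-Z scores, per-cell AUC scores, IF H-score.

Three scoring regimes cover the study's levels of observation:

* **mean-Z** — bulk cohorts: per-gene z-scores across samples, averaged over
  a signature's genes to give one score per sample/patient;
* **AUC recovery-curve** — single cells: each cell's genes are ranked by
  decreasing expression and the score is the area under the curve counting
  how many signature genes are recovered within the top ``auc_max_frac`` of
  ranks (the AUCell-style ``aucMaxRank`` cutoff), normalised by the
  perfect-recovery area so the score lies in [0, 1];
* **H-score** — immunofluorescence: ``100*(1*%weak + 2*%moderate +
  3*%strong)`` over all nuclei (negatives in the denominator), range 0-300.

The AUC score is purely rank-based, hence invariant to any per-cell monotone
transform of expression — library-size normalisation does not change it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from vmsig.io_formats import CountMatrix, ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureScoreTable",
    "CellScore",
    "NucleusCategoryCounts",
    "zscore_genes",
    "mean_z_signature_score",
    "aucell_score",
    "h_score",
]


@dataclass
class SignatureScoreTable:
    """Per-sample signature scores in mean-Z units."""

    scores: pd.Series  # index: sample identifiers, values: mean-Z score
    signature_name: str
    n_genes_used: int

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate sample identifiers in score table")
        if self.n_genes_used < 1:
            raise ValueError("n_genes_used must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return self.scores.rename("score").rename_axis("sample").reset_index()


@dataclass
class CellScore:
    """Per-cell AUC signature scores with the rank cutoff that produced them.

    ``max_rank`` is the absolute rank cutoff (``aucMaxRank``);
    ``n_signature_in_universe`` the signature size after intersection with
    the expression universe.
    """

    auc: pd.Series  # index: cell identifiers, values in [0, 1]
    max_rank: int
    signature_name: str
    n_signature_in_universe: int

    def __post_init__(self) -> None:
        vals = self.auc.to_numpy(dtype=float)
        if vals.size and ((vals < 0) | (vals > 1)).any():
            raise ValueError("AUC values must lie in [0, 1]")
        if self.max_rank < 1:
            raise ValueError("max_rank must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return self.auc.rename("auc").rename_axis("cell").reset_index()


@dataclass(frozen=True)
class NucleusCategoryCounts:
    """Counts of nuclei per staining-intensity category."""

    n_negative: int
    n_weak: int
    n_moderate: int
    n_strong: int

    def __post_init__(self) -> None:
        for f in (self.n_negative, self.n_weak, self.n_moderate, self.n_strong):
            if f < 0:
                raise ValueError("category counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_negative + self.n_weak + self.n_moderate + self.n_strong


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score every gene row across samples (sample sd, divisor n-1).

    Zero-variance genes cannot be standardised and are removed with a
    logged list.  Requires at least two samples.
    """
    if m.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    vals = m.values
    sd = vals.std(axis=1, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        dropped = list(m.gene_ids[zero_var])
        logger.warning("zscore_genes: removed %d zero-variance genes: %s%s",
                       len(dropped), dropped[:10], " ..." if len(dropped) > 10 else "")
        vals = vals.loc[~zero_var]
        sd = sd[~zero_var]
    z = vals.sub(vals.mean(axis=1), axis=0).div(sd, axis=0)
    return ExpressionMatrix(z, value_scale="zscore")


def mean_z_signature_score(z: ExpressionMatrix, sig: GeneSet) -> SignatureScoreTable:
    """Mean z-score over a signature's genes, per sample.

    The signature is intersected with the matrix's gene universe; a reduced
    intersection is logged, an empty one is an error.
    """
    if z.value_scale != "zscore":
        raise ValueError("mean_z_signature_score requires a z-scored matrix")
    present = sorted(sig.intersect(z.gene_ids))
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    if len(present) < len(sig):
        logger.warning("signature %r: %d of %d genes present in matrix",
                       sig.name, len(present), len(sig))
    scores = z.values.loc[present].mean(axis=0)
    return SignatureScoreTable(scores=scores, signature_name=sig.name,
                               n_genes_used=len(present))


def _perfect_recovery_area(m: int, g: int) -> int:
    # sum_{k=1..m} min(k, g)
    if m <= g:
        return m * (m + 1) // 2
    return g * (g + 1) // 2 + (m - g) * g


def aucell_score(
    expr: CountMatrix | ExpressionMatrix,
    sig: GeneSet,
    auc_max_frac: float = 0.10,
    tie_mode: Literal["identifier", "random"] = "identifier",
    seed: int | None = None,
) -> CellScore:
    """AUC recovery-curve score of a signature, per cell.

    For each cell the ``N`` universe genes are ranked by decreasing
    expression.  With ``m = ceil(auc_max_frac * N)`` and ``g`` signature
    genes in the universe, the score is::

        auc = sum_{k=1..m} H(k) / sum_{k=1..m} min(k, g)

    where ``H(k)`` counts signature genes at rank <= k.  The score is 1 when
    the signature occupies the very top of the ranking and 0 when no
    signature gene lies within the top ``m``.

    Ties (dominated by the zero counts of sparse cells) break by gene
    identifier ascending by default; ``tie_mode='random'`` breaks them by a
    seeded per-cell random order instead.
    """
    if not (0 < auc_max_frac <= 1):
        raise ValueError("auc_max_frac must lie in (0, 1]")

    if isinstance(expr, CountMatrix):
        gene_ids, cell_ids = expr.gene_ids, expr.cell_ids
        dense = expr.counts.toarray().astype(float)
    else:
        gene_ids, cell_ids = expr.gene_ids, expr.sample_ids
        dense = expr.values.to_numpy(dtype=float)

    n_genes, n_cells = dense.shape
    present = sig.intersect(gene_ids)
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the universe")
    g = len(present)
    m = math.ceil(auc_max_frac * n_genes)
    denom = _perfect_recovery_area(m, g)
    is_sig = np.asarray(gene_ids.isin(present))

    # identifier tie order: position of each gene in the lexicographic order
    id_order = np.argsort(np.argsort(gene_ids.to_numpy()))
    rng = np.random.default_rng(seed) if tie_mode == "random" else None
    if tie_mode not in ("identifier", "random"):
        raise ValueError("tie_mode must be 'identifier' or 'random'")

    aucs = np.empty(n_cells, dtype=float)
    for c in range(n_cells):
        tie_key = rng.permutation(n_genes) if rng is not None else id_order
        # lexsort: last key is primary -> sort by -expr, then tie key ascending
        order = np.lexsort((tie_key, -dense[:, c]))
        ranks = np.empty(n_genes, dtype=np.int64)
        ranks[order] = np.arange(1, n_genes + 1)
        sig_ranks = ranks[is_sig]
        top = sig_ranks[sig_ranks <= m]
        aucs[c] = float((m - top + 1).sum()) / denom
    return CellScore(
        auc=pd.Series(aucs, index=cell_ids),
        max_rank=m,
        signature_name=sig.name,
        n_signature_in_universe=g,
    )


def h_score(c: NucleusCategoryCounts) -> float:
    """Immunofluorescence H-score in [0, 300].

    ``100 * (1*f_weak + 2*f_moderate + 3*f_strong)`` where the fractions are
    over all nuclei, negatives included in the denominator.
    """
    total = c.total
    if total == 0:
        raise ValueError("H-score requires at least one nucleus")
    return 100.0 * (c.n_weak + 2 * c.n_moderate + 3 * c.n_strong) / total
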