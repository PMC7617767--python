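"""Single-cell stages: QC, normalisation, CellTag tumor calls, endo-high
classification, marker ranking and pseudo-bulk aggregation.

The pipeline reproduces the single-cell arm of the vasculogenic-mimicry
analysis: cells pass quality control on unique feature counts and
mitochondrial percentage; features must be detected in a minimum number of
cells in at least one sample; clusters are called *tumor* when more than a
fifth of their cells express the CellTag lineage barcode; each tumor cell
receives an endothelial-signature AUC score and the top 5% form the
*endo-high* population; markers of that population (log2 fold change of
linearised means, rank-sum p, BH q) feed pre-ranked GSEA; and cluster
counts can be aggregated per sample into pseudo-bulk profiles.

Normalisation is log1p of library-size-scaled counts.  The downstream AUC
score is rank-based within each cell, so any per-cell monotone
normalisation yields identical scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from vmsig.gsea import bh_fdr
from vmsig.io_formats import CountMatrix, ExpressionMatrix
from vmsig.scoring import CellScore

logger = logging.getLogger(__name__)

__all__ = [
    "CellAnnotation",
    "ScConfig",
    "MarkerResult",
    "qc_filter",
    "lognormalize",
    "classify_tumor_clusters",
    "classify_endo_high",
    "fraction_above_cutoff",
    "rank_markers",
    "pseudo_bulk",
]


class CellAnnotation:
    """Per-cell metadata: sample, cluster, QC covariates, CellTag status."""

    COLUMNS = ("cell", "sample", "cluster", "n_features", "mito_pct", "celltag_positive")

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"cell annotation missing columns {missing}")
        df = data.loc[:, list(self.COLUMNS)].reset_index(drop=True).copy()
        df["cell"] = df["cell"].astype(str)
        if df["cell"].duplicated().any():
            raise ValueError("duplicate cell identifiers in annotation")
        mito = df["mito_pct"].to_numpy(dtype=float)
        if ((mito < 0) | (mito > 100)).any():
            raise ValueError("mito_pct must lie in [0, 100]")
        if (df["n_features"].to_numpy(dtype=int) < 0).any():
            raise ValueError("n_features must be >= 0")
        df["celltag_positive"] = df["celltag_positive"].astype(bool)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cells(self) -> pd.Index:
        return pd.Index(self.data["cell"])

    def indexed(self) -> pd.DataFrame:
        return self.data.set_index("cell")

    def subset(self, cells: Sequence[str]) -> "CellAnnotation":
        df = self.indexed().loc[list(cells)].reset_index()
        return CellAnnotation(df)


@dataclass(frozen=True)
class ScConfig:
    """Single-cell pipeline parameters.

    QC keeps cells with ``min_features <= n_features <= max_features``
    (inclusive) and ``mito_pct < max_mito_pct`` (strict); features must be
    detected in at least ``min_cells_per_feature`` cells of at least one
    sample.  A cluster is tumor when its CellTag-positive fraction is
    strictly above ``celltag_min_frac``; the endo-high population is the
    top ``endo_top_frac`` of AUC scores.
    """

    min_features: int = 200
    max_features: int = 9000
    max_mito_pct: float = 10.0
    min_cells_per_feature: int = 5
    celltag_min_frac: float = 0.20
    endo_top_frac: float = 0.05
    norm_scale: float = 1e4
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.min_features > self.max_features:
            raise ValueError("min_features must be <= max_features")
        for name in ("celltag_min_frac", "endo_top_frac"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.norm_scale <= 0:
            raise ValueError("norm_scale must be > 0")


def qc_filter(
    counts: CountMatrix, ann: CellAnnotation, cfg: ScConfig = ScConfig()
) -> tuple[CountMatrix, CellAnnotation]:
    """Apply cell- then feature-level quality control.

    Cells survive with feature counts within ``[min_features, max_features]``
    (inclusive) and mitochondrial percentage strictly below
    ``max_mito_pct``.  Features then survive when detected (count > 0) in at
    least ``min_cells_per_feature`` surviving cells of at least one sample.
    """
    idx = ann.indexed()
    missing = counts.cell_ids.difference(idx.index)
    if len(missing):
        raise ValueError(f"annotation missing cells: {list(missing[:5])}")
    meta = idx.loc[counts.cell_ids]

    nf = meta["n_features"].to_numpy(dtype=float)
    mito = meta["mito_pct"].to_numpy(dtype=float)
    keep_cells = (
        (nf >= cfg.min_features) & (nf <= cfg.max_features) & (mito < cfg.max_mito_pct)
    )
    n_low = int((nf < cfg.min_features).sum())
    n_high = int((nf > cfg.max_features).sum())
    n_mito = int((mito >= cfg.max_mito_pct).sum())
    if not keep_cells.any():
        raise ValueError("no cell survives QC")
    cells_kept = counts.cell_ids[keep_cells]
    sub = counts.subset(cells=cells_kept)
    meta_kept = meta.loc[cells_kept]

    # feature survives if detected in >= min_cells_per_feature cells of ANY sample
    detected = sub.counts.copy()
    detected.data = np.ones_like(detected.data)
    keep_features = np.zeros(len(sub.gene_ids), dtype=bool)
    for sample in meta_kept["sample"].unique():
        cols = np.flatnonzero((meta_kept["sample"] == sample).to_numpy())
        per_sample = np.asarray(detected[:, cols].sum(axis=1)).ravel()
        keep_features |= per_sample >= cfg.min_cells_per_feature
    if not keep_features.any():
        raise ValueError("no feature survives QC")
    out = sub.subset(genes=sub.gene_ids[keep_features])
    logger.info(
        "qc_filter: removed %d cells (low features %d, high features %d, mito %d), "
        "%d features; kept %d cells x %d features",
        int((~keep_cells).sum()), n_low, n_high, n_mito,
        int((~keep_features).sum()), out.shape[1], out.shape[0],
    )
    return out, ann.subset(out.cell_ids)


def lognormalize(counts: CountMatrix, cfg: ScConfig = ScConfig()) -> ExpressionMatrix:
    """Library-size normalise and log-transform counts.

    ``value(g, c) = ln(1 + count(g, c) * norm_scale / total(c))``; zeros map
    to zeros, and scaling is per cell, so doubling a cell's counts leaves
    its normalised values unchanged.
    """
    totals = counts.cell_totals()
    zero = totals == 0
    if zero.any():
        bad = list(counts.cell_ids[zero][:5])
        raise ValueError(f"cells with zero total counts: {bad}")
    mat = counts.counts.astype(float).multiply(cfg.norm_scale / totals[np.newaxis, :])
    mat = mat.tocsr()
    mat.data = np.log1p(mat.data)
    dense = pd.DataFrame(mat.toarray(), index=counts.gene_ids, columns=counts.cell_ids)
    return ExpressionMatrix(dense, value_scale="log")


def classify_tumor_clusters(
    ann: CellAnnotation, cfg: ScConfig = ScConfig()
) -> dict[str, str]:
    """Call clusters tumor / non_tumor from their CellTag-positive fraction.

    A cluster is tumor iff strictly more than ``celltag_min_frac`` of its
    cells are CellTag-positive.
    """
    df = ann.data
    if df["cluster"].nunique() == 0:
        raise ValueError("no cluster labels")
    frac = df.groupby("cluster")["celltag_positive"].mean()
    return {
        str(cluster): ("tumor" if f > cfg.celltag_min_frac else "non_tumor")
        for cluster, f in frac.items()
    }


def classify_endo_high(
    scores: CellScore,
    cfg: ScConfig = ScConfig(),
    within: Sequence[str] | None = None,
) -> tuple[dict[str, str], float]:
    """Label the top fraction of AUC scores as endo-high.

    Selects ``k = ceil(endo_top_frac * n)`` cells with the highest scores
    within the selection universe (all scored cells by default); boundary
    ties break by cell identifier ascending.  Returns the labels and the
    lowest selected score (the operative threshold).
    """
    auc = scores.auc
    if within is not None:
        universe = pd.Index([str(c) for c in within])
        missing = universe.difference(auc.index)
        if len(missing):
            raise ValueError(f"cells absent from scores: {list(missing[:5])}")
        auc = auc.loc[universe]
    n = len(auc)
    if n == 0:
        raise ValueError("empty selection universe")
    if n < 20:
        logger.warning("classify_endo_high: only %d cells in the selection universe", n)
    k = math.ceil(cfg.endo_top_frac * n)
    ordered = auc.sort_index().sort_values(ascending=False, kind="stable")
    if k < n and ordered.iloc[k - 1] == ordered.iloc[k]:
        logger.warning("classify_endo_high: score ties at the selection boundary "
                       "broken by cell identifier")
    selected = set(ordered.index[:k])
    threshold = float(ordered.iloc[k - 1])
    labels = {c: ("endo_high" if c in selected else "rest") for c in auc.index}
    return labels, threshold


def fraction_above_cutoff(
    scores: CellScore,
    ann: CellAnnotation,
    cutoff: float,
    group_by: str = "sample",
) -> pd.DataFrame:
    """Per group, the fraction of cells scoring strictly above a cutoff."""
    if not (0 <= cutoff <= 1):
        raise ValueError("cutoff must lie in [0, 1]")
    meta = ann.indexed()
    common = scores.auc.index.intersection(meta.index)
    groups = meta.loc[common, group_by]
    rows = []
    for grp in pd.unique(groups):
        members = common[groups == grp]
        if len(members) == 0:  # pragma: no cover - defensive
            logger.warning("group %r is empty; fraction undefined", grp)
            rows.append({"group": grp, "fraction": np.nan})
            continue
        frac = float((scores.auc.loc[members] > cutoff).mean())
        rows.append({"group": grp, "fraction": frac})
    return pd.DataFrame(rows)


class MarkerResult(NamedTuple):
    """Ranked markers with per-gene statistics."""

    ranked: "RankedList"
    table: pd.DataFrame  # columns: gene, log2fc, p, q


def rank_markers(
    expr: ExpressionMatrix,
    labels: Mapping[str, str],
    pseudocount_rate: float = 1e-4,
    min_pct: float | None = None,
    min_abs_lfc: float | None = None,
) -> MarkerResult:
    """Rank genes by endo-high vs rest log2 fold change.

    Fold changes use linearised means (``expm1`` of the log-scale values)
    with a small rate pseudocount: ``log2((mean_hi + pc) / (mean_rest +
    pc))``.  Per-gene two-sided rank-sum p-values and BH q-values accompany
    the ranking.  By default every gene is retained (no min-pct / min-lfc
    prefilter) so the downstream GSEA sees the full universe; the optional
    prefilters mirror find-markers-style defaults.
    """
    from vmsig.io_formats import RankedList

    lab = pd.Series(dict(labels))
    lab.index = lab.index.astype(str)
    hi_cells = lab.index[lab == "endo_high"]
    rest_cells = lab.index[lab == "rest"]
    if len(hi_cells) == 0 or len(rest_cells) == 0:
        raise ValueError("both endo_high and rest groups must be non-empty")
    vals = expr.values
    if expr.value_scale == "log":
        lin = np.expm1(vals.to_numpy(dtype=float))
    else:
        lin = vals.to_numpy(dtype=float)
    cols = vals.columns
    hi_idx = cols.get_indexer(hi_cells)
    rest_idx = cols.get_indexer(rest_cells)
    if (hi_idx < 0).any() or (rest_idx < 0).any():
        raise ValueError("labelled cells absent from the expression matrix")

    mean_hi = lin[:, hi_idx].mean(axis=1)
    mean_rest = lin[:, rest_idx].mean(axis=1)
    lfc = np.log2((mean_hi + pseudocount_rate) / (mean_rest + pseudocount_rate))

    x = vals.to_numpy(dtype=float)
    res = stats.mannwhitneyu(
        x[:, hi_idx], x[:, rest_idx], alternative="two-sided",
        method="asymptotic", axis=1,
    )
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))  # constant genes: no effect
    q = np.asarray(bh_fdr(list(p)))

    table = pd.DataFrame({"gene": vals.index, "log2fc": lfc, "p": p, "q": q})
    if min_pct is not None:
        pct_hi = (lin[:, hi_idx] > 0).mean(axis=1)
        pct_rest = (lin[:, rest_idx] > 0).mean(axis=1)
        table = table[np.maximum(pct_hi, pct_rest) >= min_pct]
    if min_abs_lfc is not None:
        table = table[table["log2fc"].abs() >= min_abs_lfc]
    series = pd.Series(table["log2fc"].to_numpy(), index=table["gene"]).sort_index()
    return MarkerResult(ranked=RankedList(series), table=table.reset_index(drop=True))


def pseudo_bulk(
    counts: CountMatrix, ann: CellAnnotation, cluster: str
) -> ExpressionMatrix:
    """Sum a cluster's counts per gene per sample (linear counts).

    Column sums equal the summed library sizes of the contributing cells.
    """
    meta = ann.indexed().loc[counts.cell_ids]
    in_cluster = meta["cluster"].astype(str) == str(cluster)
    if not in_cluster.any():
        raise ValueError(f"cluster {cluster!r} has no cells")
    samples = sorted(meta.loc[in_cluster, "sample"].unique())
    out = {}
    for sample in samples:
        cols = np.flatnonzero((in_cluster & (meta["sample"] == sample)).to_numpy())
        out[sample] = np.asarray(counts.counts[:, cols].sum(axis=1)).ravel()
    df = pd.DataFrame(out, index=counts.gene_ids)
    return ExpressionMatrix(df, value_scale="linear")
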