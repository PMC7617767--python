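"""Cohort-level ranking metrics and group comparisons.

Three ranking metrics feed the pre-ranked GSEA engine:

* **correlation ranking** — a core signature's per-sample mean-Z score is
  correlated against every gene's expression row; the correlation
  coefficients are the ranking metric (the clinical-cohort construction);
* **median difference** — per gene, the median over a target group of
  samples minus the global median (the VM-proficient cell-line metric);
* **mean-Z difference** — per gene/protein, difference of group mean
  z-scores (the proteomics metric).

Signature-score group contrasts use the two-sided Wilcoxon rank-sum
(Mann-Whitney) test, exact for small tie-free groups and tie/continuity
corrected normal approximation otherwise.
"""

from __future__ import annotations

import logging
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from vmsig.io_formats import ExpressionMatrix, GeneSet, RankedList
from vmsig.scoring import SignatureScoreTable, mean_z_signature_score, zscore_genes

logger = logging.getLogger(__name__)

__all__ = [
    "as_group_series",
    "drop_samples",
    "rank_by_correlation",
    "rank_by_median_diff",
    "rank_by_mean_z_diff",
    "compare_groups_ranksum",
]


def as_group_series(group: Mapping[str, str] | pd.Series) -> pd.Series:
    """Normalise group labels to a sample-indexed Series of strings."""
    s = pd.Series(dict(group)) if not isinstance(group, pd.Series) else group.copy()
    s.index = s.index.astype(str)
    return s.astype(str)


def _check_groups(group: pd.Series, sample_ids: pd.Index, labels: Sequence[str]) -> None:
    unknown = group.index.difference(sample_ids)
    if len(unknown):
        raise ValueError(f"labeled samples absent from the matrix: {list(unknown[:5])}")
    for lab in labels:
        if not (group == lab).any():
            raise ValueError(f"group label {lab!r} has no samples")


def drop_samples(m: ExpressionMatrix, exclude: Sequence[str]) -> ExpressionMatrix:
    """Remove an exclusion list of samples (e.g. hematopoietic cell lines)
    before re-z-scoring."""
    keep = [s for s in m.sample_ids if s not in set(exclude)]
    if not keep:
        raise ValueError("sample exclusion removed every sample")
    n_dropped = m.shape[1] - len(keep)
    if n_dropped:
        logger.info("drop_samples: removed %d samples", n_dropped)
    return m.subset_samples(keep)


def _rowwise_pearson(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    rows_c = rows - rows.mean(axis=1, keepdims=True)
    v_c = v - v.mean()
    denom = np.sqrt((rows_c**2).sum(axis=1)) * np.sqrt((v_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rows_c @ v_c) / denom


def rank_by_correlation(
    m: ExpressionMatrix,
    core: GeneSet,
    method: Literal["pearson", "spearman"] = "pearson",
    correlate_zscored: bool = False,
    exclude_core: bool = False,
) -> RankedList:
    """Rank genes by correlation with a core signature's mean-Z score.

    The matrix is z-scored per gene, the core set's mean-Z score computed
    per sample, and every gene's expression row (raw by default,
    z-scored rows with ``correlate_zscored=True`` — for Pearson the two give
    identical coefficients since z-scoring is linear per gene) correlated
    against that score vector.  Zero-variance genes have undefined
    correlation and are excluded with a logged count.  Core genes stay in
    the list unless ``exclude_core``.
    """
    if m.shape[1] < 3:
        raise ValueError("correlation ranking requires at least 3 samples")
    z = zscore_genes(m)
    score = mean_z_signature_score(z, core).scores.to_numpy()

    source = z if correlate_zscored else m
    rows = source.values.to_numpy(dtype=float)
    if method == "pearson":
        corr = _rowwise_pearson(rows, score)
    elif method == "spearman":
        ranked_rows = stats.rankdata(rows, axis=1)
        corr = _rowwise_pearson(ranked_rows, stats.rankdata(score))
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")

    series = pd.Series(corr, index=source.gene_ids)
    bad = ~np.isfinite(series.to_numpy())
    if bad.any():
        logger.warning("rank_by_correlation: excluded %d genes with undefined correlation",
                       int(bad.sum()))
        series = series[~bad]
    if exclude_core:
        series = series[~series.index.isin(core.members)]
        logger.info("rank_by_correlation: core genes excluded from the ranked list")
    # identifier-sorted input makes metric ties break by gene id
    return RankedList(series.sort_index())


def rank_by_median_diff(
    m: ExpressionMatrix, group: Mapping[str, str] | pd.Series, target_label: str
) -> RankedList:
    """Per gene: median over the target group minus the global median."""
    if m.shape[1] < 2:
        raise ValueError("median-difference ranking requires at least 2 samples")
    g = as_group_series(group)
    _check_groups(g, m.sample_ids, [target_label])
    target_samples = g.index[g == target_label]
    target_median = m.values.loc[:, target_samples].median(axis=1)
    global_median = m.values.median(axis=1)
    metric = (target_median - global_median).sort_index()
    return RankedList(metric)


def rank_by_mean_z_diff(
    z: ExpressionMatrix,
    group: Mapping[str, str] | pd.Series,
    label_a: str,
    label_b: str,
) -> RankedList:
    """Per gene: mean z-score of group a minus mean z-score of group b."""
    if z.value_scale != "zscore":
        raise ValueError("rank_by_mean_z_diff requires a z-scored matrix")
    g = as_group_series(group)
    _check_groups(g, z.sample_ids, [label_a, label_b])
    a = g.index[g == label_a]
    b = g.index[g == label_b]
    metric = (z.values.loc[:, a].mean(axis=1) - z.values.loc[:, b].mean(axis=1)).sort_index()
    return RankedList(metric)


def compare_groups_ranksum(
    scores: SignatureScoreTable | pd.Series,
    group: Mapping[str, str] | pd.Series,
    label_a: str,
    label_b: str,
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of signature scores.

    Exact enumeration when both groups are small (min n <= 8) and tie-free,
    otherwise the tie- and continuity-corrected normal approximation.  The
    test has little power below a total of 8 samples; smaller inputs warn.
    Returns ``{'statistic', 'p_two_sided', 'n_a', 'n_b'}``.
    """
    s = scores.scores if isinstance(scores, SignatureScoreTable) else scores
    g = as_group_series(group)
    _check_groups(g, s.index, [label_a, label_b])
    a = s.loc[g.index[g == label_a]].to_numpy(dtype=float)
    b = s.loc[g.index[g == label_b]].to_numpy(dtype=float)
    if len(a) + len(b) < 8:
        logger.warning("rank-sum comparison with n_a + n_b = %d < 8: little power",
                       len(a) + len(b))
    tie_free = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "statistic": float(res.statistic),
        "p_two_sided": float(min(res.pvalue, 1.0)),
        "n_a": len(a),
        "n_b": len(b),
    }
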