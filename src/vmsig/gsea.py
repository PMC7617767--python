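"""Pre-ranked gene-set enrichment analysis with a weighted KS statistic.

Given a list of genes ranked by a real metric, the enrichment score (ES) of
a gene set is the maximal deviation between two running distributions walked
down the list: hits accumulate the metric weights ``|r|^p`` of set members
(normalised by their total), misses accumulate uniformly over non-members.
With ``p = 0`` this is the classical two-sample Kolmogorov-Smirnov statistic;
``p = 1`` (the default) weights each hit by its metric magnitude.

Significance uses gene-set permutation: the null ES distribution for a set
of matched size ``g`` comes from ``n_perm`` random size-``g`` draws from the
ranked universe.  The normalised ES (NES) divides the observed ES by the
mean magnitude of same-sign null ES values; the FDR q-value compares the
pooled normalised null distribution against the observed NES distribution
(the normalised-null ratio method), clamped to [0, 1].  All draws are seeded
and results are deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from vmsig.io_formats import GeneSet, GeneSetCollection, RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "GseaConfig",
    "EnrichmentResult",
    "EnrichmentProfile",
    "enrichment_score",
    "gsea_preranked",
    "bh_fdr",
    "signed_log10_q",
    "results_to_frame",
]


@dataclass(frozen=True)
class GseaConfig:
    """Parameters of the pre-ranked GSEA run.

    ``weight_p`` is the hit-weight exponent (0 = unweighted KS, 1 = classic
    weighted default); ``n_perm`` the number of gene-set permutations for the
    null; sets whose matched size falls outside
    ``[min_set_size, max_set_size]`` are skipped.
    """

    weight_p: float = 1.0
    n_perm: int = 1000
    seed: int = 0
    min_set_size: int = 5
    max_set_size: int = 2000

    def __post_init__(self) -> None:
        if self.weight_p < 0:
            raise ValueError("weight_p must be >= 0")
        if self.n_perm < 10:
            raise ValueError("n_perm must be >= 10")
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size must be <= max_set_size")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class EnrichmentResult:
    """Enrichment statistics for one gene set on one ranked list."""

    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    signed_log10_q: float
    leading_edge: list[str]
    n_genes_matched: int


class EnrichmentProfile(NamedTuple):
    """Raw output of a single enrichment-score walk."""

    es: float
    running: np.ndarray  # deviation P_hit - P_miss at every list index
    leading_edge: list[str]


def _hit_weights(metrics: np.ndarray, weight_p: float) -> np.ndarray:
    return np.abs(metrics) ** weight_p


def enrichment_score(
    ranked: RankedList, sig: GeneSet, weight_p: float = 1.0
) -> EnrichmentProfile:
    """Weighted KS enrichment score of ``sig`` on ``ranked``.

    Walks the ranked list accumulating ``P_hit`` (metric-weighted over set
    members) and ``P_miss`` (uniform over non-members); the ES is the
    deviation ``P_hit - P_miss`` of maximal absolute value, with an exact tie
    between equal-magnitude positive and negative extremes resolved to the
    positive one.  The leading edge contains the set members at or before
    the extremum for positive ES, at or after it for negative ES.
    """
    genes = ranked.genes
    n = len(genes)
    hit = np.asarray(genes.isin(sig.members))
    n_s = int(hit.sum())
    if n_s == 0:
        raise ValueError(f"no gene of {sig.name!r} in the ranked list")
    if n_s == n:
        raise ValueError(f"{sig.name!r} covers the whole ranked list (empty complement)")

    w = _hit_weights(ranked.metrics, weight_p) * hit
    n_r = w.sum()
    if n_r == 0:
        logger.warning("all matched metrics are zero for %r; using equal hit weights",
                       sig.name)
        w = hit.astype(float)
        n_r = w.sum()
    p_hit = np.cumsum(w) / n_r
    p_miss = np.cumsum(~hit) / (n - n_s)
    running = p_hit - p_miss

    pos_extreme = float(running.max())
    neg_extreme = float(running.min())
    # ties between equal-magnitude extremes resolve positive; detect them
    # within float tolerance so rounding cannot flip the documented rule
    tol = 1e-12 * (pos_extreme - neg_extreme)
    if pos_extreme + neg_extreme >= -tol:
        es = pos_extreme
        peak = int(np.argmax(running))
        le_mask = hit & (np.arange(n) <= peak)
    else:
        es = neg_extreme
        trough = int(np.argmin(running))
        le_mask = hit & (np.arange(n) >= trough)
    leading_edge = list(genes[le_mask]) if es != 0 else []
    es = float(np.clip(es, -1.0, 1.0))  # guard float accumulation overshoot
    return EnrichmentProfile(es=es, running=running, leading_edge=leading_edge)


def _es_batch(weights: np.ndarray, positions: np.ndarray, n: int) -> np.ndarray:
    """ES for many hit-position vectors at once.

    ``weights``: per-position hit weights ``|r|^p`` over the full list
    (length ``n``); ``positions``: (B, g) 0-based hit positions, sorted
    ascending per row.  Exploits that the running deviation attains its
    maximum immediately after a hit and its minimum immediately before one.
    """
    b, g = positions.shape
    wp = weights[positions]                       # (B, g)
    n_r = wp.sum(axis=1, keepdims=True)           # (B, 1)
    zero = n_r[:, 0] == 0
    if zero.any():
        wp = wp.copy()
        wp[zero] = 1.0
        n_r = wp.sum(axis=1, keepdims=True)
    cum_w = np.cumsum(wp, axis=1) / n_r           # P_hit just after each hit
    idx = np.arange(1, g + 1)
    denom_miss = n - g
    # misses passed just after the i-th hit: (pos_i + 1) - i   (i 1-based)
    dev_after = cum_w - (positions + 1 - idx) / denom_miss
    # running just before the i-th hit: P_hit = cum_w[i-1], misses = pos_i - (i-1)
    cum_w_prev = np.concatenate([np.zeros((b, 1)), cum_w[:, :-1]], axis=1)
    dev_before = cum_w_prev - (positions - (idx - 1)) / denom_miss
    pos_extreme = dev_after.max(axis=1)
    neg_extreme = dev_before.min(axis=1)
    tol = 1e-12 * (pos_extreme - neg_extreme)
    es = np.where(pos_extreme + neg_extreme >= -tol, pos_extreme, neg_extreme)
    return np.clip(es, -1.0, 1.0)


def _null_es(
    weights: np.ndarray, n: int, size: int, n_perm: int, seed: int
) -> np.ndarray:
    """Null ES from ``n_perm`` random size-``size`` draws (seeded by size).

    Seeding by (seed, size) makes the null for a given matched size
    reproducible and shareable across sets of that size within a run.
    """
    rng = np.random.default_rng([seed, size])
    u = rng.random((n_perm, n))
    positions = np.sort(np.argsort(u, axis=1)[:, :size], axis=1)
    return _es_batch(weights, positions, n)


def _nes(es: float | np.ndarray, null: np.ndarray) -> float | np.ndarray:
    """Normalise ES by the mean magnitude of same-sign null values."""
    pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
    neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
    scalar = np.isscalar(es)
    es_arr = np.atleast_1d(np.asarray(es, dtype=float))
    scale = np.where(es_arr >= 0, pos_mean, neg_mean)
    fallback = np.abs(null).mean() if null.size else np.nan
    scale = np.where(np.isnan(scale), fallback, scale)
    out = np.where(es_arr == 0, 0.0, es_arr / scale)
    return float(out[0]) if scalar else out


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection | Sequence[GeneSet],
    cfg: GseaConfig = GseaConfig(),
) -> list[EnrichmentResult]:
    """Run pre-ranked GSEA for a collection of gene sets.

    Per set (after filtering on matched size): the observed ES and leading
    edge; a seeded permutation null of same-size random draws; NES; the
    add-one nominal p ``(b + 1) / (n_same_sign + 1)``; and the FDR q from the
    pooled normalised null (clamped to [0, 1]).  The signed ``-log10(q)``
    summary uses a floor of ``1 / (n_perm + 1)``.
    """
    n = len(ranked)
    if n < cfg.min_set_size + 1:
        raise ValueError("ranked list shorter than min_set_size + 1")
    weights = _hit_weights(ranked.metrics, cfg.weight_p)
    genes = ranked.genes

    kept: list[tuple[GeneSet, int]] = []
    for gs in sets:
        matched = int(genes.isin(gs.members).sum())
        if matched < cfg.min_set_size or matched > cfg.max_set_size or matched == n:
            logger.info("skipping set %r (matched size %d)", gs.name, matched)
            continue
        kept.append((gs, matched))
    if not kept:
        raise ValueError("all gene sets were filtered out by matched-size limits")

    # one permutation null per distinct matched size, shared across sets
    null_by_size: dict[int, np.ndarray] = {}
    null_nes_by_size: dict[int, np.ndarray] = {}
    for _, size in kept:
        if size not in null_by_size:
            null = _null_es(weights, n, size, cfg.n_perm, cfg.seed)
            null_by_size[size] = null
            null_nes_by_size[size] = np.asarray(_nes(null, null))

    results: list[EnrichmentResult] = []
    observed_nes: list[float] = []
    for gs, size in kept:
        profile = enrichment_score(ranked, gs, cfg.weight_p)
        null = null_by_size[size]
        nes = float(_nes(profile.es, null))
        same_sign = null[null > 0] if profile.es >= 0 else null[null < 0]
        b = int((np.abs(same_sign) >= abs(profile.es)).sum())
        p_nom = (b + 1) / (len(same_sign) + 1)
        results.append(
            EnrichmentResult(
                set_name=gs.name,
                es=profile.es,
                nes=nes,
                p_nominal=p_nom,
                fdr_q=np.nan,  # filled below from the pooled null
                signed_log10_q=np.nan,
                leading_edge=profile.leading_edge,
                n_genes_matched=size,
            )
        )
        observed_nes.append(nes)

    pooled_null_nes = np.concatenate([null_nes_by_size[s] for s in sorted(null_nes_by_size)])
    obs = np.asarray(observed_nes)
    q_floor = 1.0 / (cfg.n_perm + 1)
    for res in results:
        nes = res.nes
        if nes >= 0:
            null_same = pooled_null_nes[pooled_null_nes > 0]
            obs_same = obs[obs >= 0]
        else:
            null_same = pooled_null_nes[pooled_null_nes < 0]
            obs_same = obs[obs < 0]
        if null_same.size == 0:
            frac_null = 0.0
        else:
            frac_null = (np.abs(null_same) >= abs(nes)).sum() / null_same.size
        frac_obs = (np.abs(obs_same) >= abs(nes)).sum() / obs_same.size
        res.fdr_q = float(min(1.0, max(0.0, frac_null / frac_obs)))
        res.signed_log10_q = signed_log10_q(res, q_floor=q_floor)
    return results


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in q]


def signed_log10_q(res: EnrichmentResult, q_floor: float = 1e-3) -> float:
    """``sign(es) * -log10(max(fdr_q, q_floor))``.

    The floor keeps permutation q-values of 0 finite; by default use
    ``1 / (n_perm + 1)`` for the run that produced the result.
    """
    if not (0 <= res.fdr_q <= 1):
        raise ValueError("fdr_q must lie in [0, 1]")
    sign = 1.0 if res.es > 0 else (-1.0 if res.es < 0 else 0.0)
    return sign * -np.log10(max(res.fdr_q, q_floor))


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results (leading edge comma-joined)."""
    return pd.DataFrame(
        {
            "set": [r.set_name for r in results],
            "size": [r.n_genes_matched for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p_nominal for r in results],
            "q": [r.fdr_q for r in results],
            "signed_log10_q": [r.signed_log10_q for r in results],
            "leading_edge": [",".join(r.leading_edge) for r in results],
        }
    )
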