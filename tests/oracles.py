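"""Independent brute-force oracles used to pin the scoring and enrichment
implementations.

These deliberately re-derive each statistic by direct accumulation, sharing
no code with the package, so agreement is meaningful.  The enrichment walk
uses exact rational arithmetic so that equal-magnitude positive/negative
extremes (where the tie rule applies) are detected without floating-point
ambiguity.
"""

from __future__ import annotations

import math
from fractions import Fraction


def brute_force_auc(
    values: dict[str, float], signature: set[str], auc_max_frac: float
) -> float:
    """Recovery-curve AUC by explicit accumulation over every rank.

    Ranks genes by decreasing value with ties broken by identifier
    ascending, walks ranks 1..m counting recovered signature genes, and
    normalises by the perfect-recovery area.
    """
    genes = sorted(values, key=lambda g: (-values[g], g))
    n = len(genes)
    sig = signature & set(genes)
    g = len(sig)
    m = math.ceil(auc_max_frac * n)
    hits = 0
    raw = 0
    max_raw = 0
    for k in range(1, m + 1):
        if genes[k - 1] in sig:
            hits += 1
        raw += hits
        max_raw += min(k, g)
    return raw / max_raw


def brute_force_es_extremes(
    genes: list[str], metrics: list[float], members: set[str], weight_p: float
) -> tuple[Fraction, Fraction]:
    """Exact (max positive, min negative) running deviations of the
    weighted KS walk, in rational arithmetic."""
    n = len(genes)
    hit = [g in members for g in genes]
    n_s = sum(hit)
    assert 0 < n_s < n
    weights = [
        Fraction(abs(m) ** weight_p) if h else Fraction(0)
        for m, h in zip(metrics, hit)
    ]
    n_r = sum(weights)
    if n_r == 0:
        weights = [Fraction(1) if h else Fraction(0) for h in hit]
        n_r = Fraction(n_s)
    p_hit = Fraction(0)
    p_miss = Fraction(0)
    pos = Fraction(0)
    neg = Fraction(0)
    for i in range(n):
        if hit[i]:
            p_hit += weights[i] / n_r
        else:
            p_miss += Fraction(1, n - n_s)
        dev = p_hit - p_miss
        pos = max(pos, dev)
        neg = min(neg, dev)
    return pos, neg


def brute_force_es(
    genes: list[str], metrics: list[float], members: set[str], weight_p: float
) -> float:
    """Weighted KS enrichment score by a direct exact walk (positive wins an
    exact tie between equal-magnitude extremes)."""
    pos, neg = brute_force_es_extremes(genes, metrics, members, weight_p)
    return float(pos) if pos >= -neg else float(neg)
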