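"""Hypergeometric over-representation analysis with Benjamini-Hochberg FDR.

Tests each annotation term for over-representation in a query protein set
against a background (by default all proteins identified in the experiment,
the standard choice for proteomics ORA), using the upper-tail hypergeometric
probability P(X >= k) and BH step-up q-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "hypergeometric_tail", "bh_fdr", "enrich_terms"]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # query hits
    K: int  # background hits
    n: int  # query size
    N: int  # background size
    p_value: float
    q_value: float
    significant: bool


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric parameters k={k} K={K} n={n} N={N}")
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_terms(
    query: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation results for every term with >= 1 query hit.

    q-values are BH-corrected across the tested terms; results are sorted by
    p-value ascending (ties by term id) and flagged significant at q < alpha.
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    query_set = set(query)
    background_set = set(background)
    stray = query_set - background_set
    if stray:
        raise ValueError(f"query accessions missing from background: {sorted(stray)}")
    n, N = len(query_set), len(background_set)
    rows = []
    for term, members in annotations.items():
        members_bg = set(members) & background_set
        k = len(members_bg & query_set)
        if k == 0:
            continue
        rows.append((term, k, len(members_bg)))
    if not rows:
        return []
    p_values = [hypergeometric_tail(k, K, n, N) for _, k, K in rows]
    q_values = bh_fdr(p_values)
    results = [
        EnrichmentResult(term, k, K, n, N, p, float(q), bool(q < alpha))
        for (term, k, K), p, q in zip(rows, p_values, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
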