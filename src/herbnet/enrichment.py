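"""Hypergeometric over-representation analysis of target sets.

The association between a query target set (size n) and an annotated set
(disease or pathway genes, size K) in a universe of N annotatable targets is
scored by the upper tail of the hypergeometric distribution,

    P = P(X >= k) = 1 - sum_{i=0}^{k-1} C(K, i) C(N-K, n-i) / C(N, n),

where k is the observed overlap. Small P means the overlap is larger than
expected for a random draw of n targets from the universe.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import numpy as np
from scipy.special import gammaln, logsumexp

from .types import EnrichmentQuery, EnrichmentResult

__all__ = ["hypergeom_upper_tail", "rank_annotations", "benjamini_hochberg"]


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def hypergeom_upper_tail(q: EnrichmentQuery) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), in log space.

    Summed over the feasible upper tail with log-gamma binomial
    coefficients and a log-sum-exp reduction, then clamped to [0, 1].
    k = 0 returns exactly 1 (empty lower sum).
    """
    N, K, n, k = q.N, q.K, q.n, q.k
    if k == 0:
        return 1.0
    hi = min(n, K)
    lo_bound = max(0, n - (N - K))  # smallest feasible overlap
    log_denom = _log_binom(N, n)
    terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denom
        for i in range(max(k, lo_bound), hi + 1)
    ]
    if not terms:
        return 0.0
    p = float(np.exp(logsumexp(terms)))
    return min(max(p, 0.0), 1.0)


def benjamini_hochberg(pvals: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(list(pvals), dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj.tolist()


def rank_annotations(
    query_set: Set[str],
    universe: Mapping[str, Set[str]],
    alpha: float = 0.05,
    universe_size: int | None = None,
) -> list[EnrichmentResult]:
    """Rank annotations by hypergeometric upper-tail probability.

    ``universe`` maps annotation id -> annotated gene set. The universe size
    N defaults to the number of distinct genes across all annotations;
    ``universe_size`` overrides it when the annotatable space is larger than
    the union of annotated sets. Results are sorted by p ascending, then
    annotation id; significance is flagged at ``alpha`` on the raw p, and a
    Benjamini-Hochberg adjusted column is included.
    """
    if not query_set:
        raise ValueError("query set is empty")
    if not universe:
        raise ValueError("annotation universe is empty")
    space: set[str] = set()
    for genes in universe.values():
        space |= set(genes)
    N = universe_size if universe_size is not None else len(space)
    stray = set(query_set) - space if universe_size is None else set()
    if stray:
        raise ValueError(
            f"query gene(s) outside the annotation universe: {sorted(stray)[:5]}"
        )
    n = len(set(query_set))
    rows = []
    for ann_id in sorted(universe):
        genes = set(universe[ann_id])
        K = len(genes)
        k = len(genes & set(query_set))
        q = EnrichmentQuery(N=N, K=K, n=n, k=k)
        rows.append((ann_id, q, hypergeom_upper_tail(q)))
    bh = benjamini_hochberg([p for _, _, p in rows])
    indexed = sorted(
        range(len(rows)), key=lambda i: (rows[i][2], rows[i][0])
    )
    results = []
    for rank, i in enumerate(indexed, start=1):
        ann_id, q, p = rows[i]
        results.append(
            EnrichmentResult(
                annotation_id=ann_id,
                query=q,
                p=p,
                significant=p < alpha,
                rank=rank,
                bh_p=bh[i],
            )
        )
    return results
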