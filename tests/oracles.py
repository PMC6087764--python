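"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — raw loops, exact rational
arithmetic — and shares no code with the package's own computation paths.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Mapping, Sequence


def hypergeom_tail_exact(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exact rational enumeration of the lower tail."""
    denom = math.comb(N, n)
    lower = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k))
    return 1 - Fraction(lower, denom)


def pooled_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t statistic and two-sided p."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    ssa = sum((x - ma) ** 2 for x in a)
    ssb = sum((x - mb) ** 2 for x in b)
    df = na + nb - 2
    sp2 = (ssa + ssb) / df
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * t_dist.sf(abs(t), df)
    return t, p


def tanimoto_binary_naive(bits_a: Sequence[int], bits_b: Sequence[int]) -> float:
    both = sum(1 for x, y in zip(bits_a, bits_b) if x and y)
    either = sum(1 for x, y in zip(bits_a, bits_b) if x or y)
    return 0.0 if either == 0 else both / either


def contribution_scores_naive(
    edges: Sequence[tuple[str, str]],
    herb_of: Mapping[str, str],
    herbs: tuple[str, str],
    policy: str = "floor",
) -> dict[str, float]:
    """CS by direct edge enumeration: degrees counted with raw loops."""
    edges = sorted(set(edges))
    t_edges = len(edges)
    out: dict[str, float] = {}
    for c in sorted({a for a, _ in edges}):
        incident = [(a, b) for a, b in edges if a == c]
        c_i = len(incident)
        c_a = c_i if herb_of[c] == herbs[0] else 0
        c_b = c_i if herb_of[c] == herbs[1] else 0
        omega = c_i / t_edges
        if c_a == c_b:
            if policy == "floor":
                a_i = omega + (c_a + c_b)
            elif policy == "skip-term":
                a_i = omega
            else:
                raise ValueError("degenerate balanced degrees")
        else:
            a_i = omega + abs((c_a + c_b) / (c_a - c_b))
        p_sum = sum(
            sum(1 for _, b2 in edges if b2 == t) for _, t in incident
        )
        out[c] = c_i * a_i * p_sum
    return out
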