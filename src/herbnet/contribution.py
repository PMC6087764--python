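"""Per-component contribution scores on a merged two-herb C-T network.

Each component i gets an edge-weight fraction omega_i = C_i / T_edge (its
degree over the total edge count), an affinity index

    A_i = omega_i + |(C_Ai + C_Bi) / (C_Ai - C_Bi)|

combining omega with the balance of its degree across the two herb
subnetworks, and a contribution score

    CS(i) = C_i * A_i * sum_j P_j

where the sum runs over the component's targets j and P_j is the target's
degree in the merged network. Scores are reported as percentages of the
total and cumulatively in rank order, so one can read off how many
components carry a given share of the formula's predicted activity.

When a component appears in only one herb (the usual case for a two-herb
formula with disjoint ingredient sets) the ratio term is exactly 1 and
A_i = omega_i + 1. The degenerate case C_Ai = C_Bi > 0 cannot occur with
disjoint herbs but must be defined; the default policy floors the
denominator at 1 (ratio term = C_Ai + C_Bi), with ``error`` and
``skip-term`` alternatives.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

from .network import BipartiteNetwork, herb_subnetwork
from .types import ContributionResult

__all__ = [
    "edge_weight",
    "affinity_index",
    "contribution_scores",
    "cumulative_report",
]

DegeneratePolicy = Literal["floor", "error", "skip-term"]


def edge_weight(c_edges: int, t_edges: int) -> float:
    """omega = (edges incident to the component) / (total network edges)."""
    if t_edges <= 0:
        raise ValueError("total edge count must be positive")
    if not (0 <= c_edges <= t_edges):
        raise ValueError("component edge count must lie in [0, total]")
    return c_edges / t_edges


def affinity_index(
    omega: float, c_a: int, c_b: int, policy: DegeneratePolicy = "floor"
) -> float:
    """Affinity index A = omega + |(c_a + c_b) / (c_a - c_b)|.

    ``c_a`` / ``c_b`` are the component's degrees in the two herb
    subnetworks. With exactly one of them zero the ratio term is 1. For the
    degenerate balanced case ``c_a == c_b > 0`` the ``policy`` applies:
    ``floor`` (default) floors the denominator at 1, ``skip-term`` drops the
    ratio term, ``error`` raises.
    """
    if c_a < 0 or c_b < 0:
        raise ValueError("degrees must be non-negative")
    if c_a + c_b == 0:
        raise ValueError("component has no edges in either herb subnetwork")
    if c_a == c_b:
        if policy == "floor":
            return omega + float(c_a + c_b)
        if policy == "skip-term":
            return omega
        raise ValueError(f"degenerate balanced degrees c_a == c_b == {c_a}")
    return omega + abs((c_a + c_b) / (c_a - c_b))


def contribution_scores(
    net: BipartiteNetwork,
    herbs: Sequence[str] = ("ZHISHI", "BAIZHU"),
    policy: DegeneratePolicy = "floor",
    sum_over: Literal["incident", "all"] = "incident",
) -> list[ContributionResult]:
    """Contribution scores for every component of a herb-labelled C-T network.

    ``sum_over="incident"`` (default) sums target degrees P_j over the
    component's own targets; ``"all"`` sums over every target in the network
    (an alternative reading that makes the target-degree factor a global
    constant and preserves only the C_i * A_i ordering).

    Results are sorted by score descending, component id ascending, with
    percentage and cumulative-percentage columns.
    """
    if not net.edges:
        raise ValueError("network has no edges")
    missing = [n for n in net.left_nodes if n not in net.herb_of]
    if missing:
        raise ValueError(f"component(s) without herb label: {sorted(missing)}")
    herb_a, herb_b = herbs
    present = set(net.herb_of.values())
    sub = {
        h: herb_subnetwork(net, h) if h in present else None for h in (herb_a, herb_b)
    }
    deg = net.degree
    t_edges = net.n_edges
    all_target_degree_sum = sum(deg[t] for t in net.right_nodes)

    rows: list[dict] = []
    for cid in sorted(net.left_nodes):
        c_i = deg[cid]
        if c_i == 0:
            continue  # isolated components carry no contribution
        c_a = sub[herb_a].degree.get(cid, 0) if sub[herb_a] else 0
        c_b = sub[herb_b].degree.get(cid, 0) if sub[herb_b] else 0
        omega = edge_weight(c_i, t_edges)
        a_i = affinity_index(omega, c_a, c_b, policy=policy)
        if sum_over == "incident":
            p_sum = sum(deg[t] for t in net.targets_of(cid))
        else:
            p_sum = all_target_degree_sum
        cs = c_i * a_i * p_sum
        rows.append(
            dict(
                component_id=cid,
                herb=net.herb_of[cid],
                degree=c_i,
                degree_in_a=c_a,
                degree_in_b=c_b,
                omega=omega,
                affinity=a_i,
                target_degree_sum=p_sum,
                cs=cs,
            )
        )
    total = sum(r["cs"] for r in rows)
    if total <= 0:
        raise ValueError("total contribution score is zero")
    rows.sort(key=lambda r: (-r["cs"], r["component_id"]))
    results: list[ContributionResult] = []
    cum = 0.0
    for rank, r in enumerate(rows, start=1):
        pct = 100.0 * r["cs"] / total
        cum += pct
        results.append(
            ContributionResult(rank=rank, cs_pct=pct, cum_pct=min(cum, 100.0), **r)
        )
    return results


def cumulative_report(
    results: Sequence[ContributionResult], cutoff_pct: float
) -> tuple[int, float]:
    """Smallest k such that the top-k cumulative percentage reaches a cutoff.

    Returns ``(k, achieved cumulative percent)``.
    """
    if not results:
        raise ValueError("no contribution results")
    if not (0.0 < cutoff_pct <= 100.0):
        raise ValueError("cutoff must lie in (0, 100]")
    cum = 0.0
    for i, r in enumerate(results, start=1):
        cum += r.cs_pct
        if cum >= cutoff_pct - 1e-12:
            return i, cum
    # float round-off can leave the final running sum a hair under 100
    return len(results), cum
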