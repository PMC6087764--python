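"""Bipartite network construction, summaries, and Cytoscape-readable export.

Networks are simple (duplicate edges collapse), undirected, and strictly
bipartite: component-target (C-T) or target-pathway (T-P). Degrees are edge
counts per node; isolated declared nodes are retained with degree 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .types import NetworkSummary

__all__ = [
    "BipartiteNetwork",
    "build_bipartite",
    "summarize",
    "herb_subnetwork",
    "shared_targets",
    "top_degree_nodes",
    "export_sif",
    "export_graphml",
    "import_graphml",
]


@dataclass(frozen=True)
class BipartiteNetwork:
    """A simple bipartite network with optional per-left-node herb labels."""

    left_nodes: frozenset[str]
    right_nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    herb_of: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a not in self.left_nodes or b not in self.right_nodes:
                raise ValueError(f"edge ({a}, {b}) has an undeclared endpoint")

    @property
    def degree(self) -> dict[str, int]:
        deg = {n: 0 for n in self.left_nodes | self.right_nodes}
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def targets_of(self, left_node: str) -> frozenset[str]:
        return frozenset(b for a, b in self.edges if a == left_node)


def build_bipartite(
    edges: Iterable[tuple[str, str]],
    left_ids: Iterable[str] | None = None,
    right_ids: Iterable[str] | None = None,
    herb_of: Mapping[str, str] | None = None,
) -> BipartiteNetwork:
    """Build a simple bipartite network from an edge list.

    When ``left_ids``/``right_ids`` are omitted the sides are inferred from
    edge positions. An id appearing on both sides is an error. Duplicate
    edges collapse silently (the network is simple).
    """
    edge_set = frozenset((str(a), str(b)) for a, b in edges)
    left = set(str(x) for x in left_ids) if left_ids is not None else {a for a, _ in edge_set}
    right = set(str(x) for x in right_ids) if right_ids is not None else {b for _, b in edge_set}
    both = left & right
    if both:
        raise ValueError(
            f"id(s) appear on both sides of the bipartite network: {sorted(both)}"
        )
    # endpoints referenced by edges must be declared when sides are explicit
    for a, b in edge_set:
        if a not in left:
            raise ValueError(f"edge source {a!r} not in declared left nodes")
        if b not in right:
            raise ValueError(f"edge target {b!r} not in declared right nodes")
    return BipartiteNetwork(
        left_nodes=frozenset(left),
        right_nodes=frozenset(right),
        edges=edge_set,
        herb_of=dict(herb_of) if herb_of else {},
    )


def summarize(net: BipartiteNetwork) -> NetworkSummary:
    """Node/edge counts and mean degrees (full precision; round in reports)."""
    if not net.left_nodes or not net.right_nodes:
        raise ValueError("cannot summarise a network with an empty side")
    return NetworkSummary(
        n_left=len(net.left_nodes),
        n_right=len(net.right_nodes),
        n_edges=net.n_edges,
    )


def herb_subnetwork(net: BipartiteNetwork, herb: str) -> BipartiteNetwork:
    """Restrict a labelled C-T network to one herb's components.

    Right nodes are kept only if they retain at least one incident edge.
    """
    if herb not in set(net.herb_of.values()):
        raise ValueError(f"unknown herb label {herb!r}")
    left = frozenset(n for n in net.left_nodes if net.herb_of.get(n) == herb)
    edges = frozenset((a, b) for a, b in net.edges if a in left)
    right = frozenset(b for _, b in edges)
    return BipartiteNetwork(
        left_nodes=left,
        right_nodes=right,
        edges=edges,
        herb_of={n: herb for n in left},
    )


def shared_targets(net_a: BipartiteNetwork, net_b: BipartiteNetwork) -> frozenset[str]:
    """Right nodes with degree >= 1 in both networks (common targets)."""
    deg_a = net_a.degree
    deg_b = net_b.degree
    hit_a = {n for n in net_a.right_nodes if deg_a[n] >= 1}
    hit_b = {n for n in net_b.right_nodes if deg_b[n] >= 1}
    return frozenset(hit_a & hit_b)


def top_degree_nodes(
    net: BipartiteNetwork, side: str, k: int
) -> list[tuple[str, int]]:
    """Top-k nodes of one side by degree, ties broken by id ascending.

    ``side`` is ``"left"`` or ``"right"``. Asking for more nodes than the
    side holds returns the full ranking with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    nodes = net.left_nodes if side == "left" else net.right_nodes
    deg = net.degree
    ranked = sorted(nodes, key=lambda n: (-deg[n], n))
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds side size {len(ranked)}; returning full ranking",
            stacklevel=2,
        )
        k = len(ranked)
    return [(n, deg[n]) for n in ranked[:k]]


# ---------------------------------------------------------------------------
# Cytoscape-readable export


def export_sif(net: BipartiteNetwork, path: str | Path,
               interaction: str = "ct") -> None:
    """Write ``node<TAB>interaction<TAB>node`` SIF lines, sorted."""
    with open(path, "w", encoding="utf-8") as f:
        for a, b in sorted(net.edges):
            f.write(f"{a}\t{interaction}\t{b}\n")


def _to_nx(net: BipartiteNetwork) -> nx.Graph:
    g = nx.Graph()
    for n in sorted(net.left_nodes):
        g.add_node(n, side="left", herb=net.herb_of.get(n, ""))
    for n in sorted(net.right_nodes):
        g.add_node(n, side="right", herb="")
    g.add_edges_from(sorted(net.edges))
    return g


def export_graphml(net: BipartiteNetwork, path: str | Path) -> None:
    """Write GraphML with ``side`` and ``herb`` node attributes."""
    nx.write_graphml(_to_nx(net), str(path))


def import_graphml(path: str | Path) -> BipartiteNetwork:
    """Re-read a GraphML file written by :func:`export_graphml`."""
    g = nx.read_graphml(str(path))
    left = {n for n, d in g.nodes(data=True) if d.get("side") == "left"}
    right = {n for n, d in g.nodes(data=True) if d.get("side") == "right"}
    edges = set()
    for a, b in g.edges():
        if a in left:
            edges.add((a, b))
        else:
            edges.add((b, a))
    herb_of = {n: d["herb"] for n, d in g.nodes(data=True)
               if n in left and d.get("herb")}
    return BipartiteNetwork(
        left_nodes=frozenset(left),
        right_nodes=frozenset(right),
        edges=frozenset(edges),
        herb_of=herb_of,
    )
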