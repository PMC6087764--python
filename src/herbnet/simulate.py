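"""Seeded generators for every input the analysis pipeline consumes.

These emulate the statistical structure the analysis assumes — two herbs
with distinct property distributions, a merged two-source bipartite
component-target network, an annotation universe with one planted enriched
annotation, and binary substructure fingerprints — so every stage is
testable without external databases. Each generator is a pure function of
its spec plus seed: reruns are bit-identical.
"""

from __future__ import annotations

from typing import Mapping, Sequence, Set

import numpy as np

from .types import (
    Component,
    Fingerprint,
    GIClass,
    HerbProfile,
    NetworkSpec,
    PlantedEnrichmentSpec,
)

__all__ = [
    "default_herb_profiles",
    "gen_component_table",
    "gen_bipartite_edges",
    "gen_annotation_universe",
    "gen_fingerprints",
]

#: Properties drawn from clamped normals (name -> (lower, upper) clamp).
_CONTINUOUS = {
    "mw": (0.0, None),
    "ob": (0.0, None),
    "caco2": (None, None),
    "dl": (0.0, 1.0),
    "mlogp": (None, None),
    "tpsa": (0.0, None),
}
_COUNTS = ("nhacc", "nhdon")

_ID_PREFIX = {"ZHISHI": "ZS", "BAIZHU": "BZ"}


def default_herb_profiles(
    n_zhishi: int = 150, n_baizhu: int = 128
) -> list[HerbProfile]:
    """Two-herb profiles emulating the Zhishi/Baizhu property contrast.

    Means are the per-herb averages of the full (pre-screen) component
    collections: Zhishi MW 393.39 / OB 28.94 / Caco-2 -0.20 / DL 0.41 /
    MLogP 0.15 / nHAcc 7.67 / nHDon 3.50 / TPSA 51.65, versus Baizhu
    252.67 / 37.76 / 0.69 / 0.20 / 2.10 / 2.95 / 1.54 / 120.45.
    Dispersions are not published; the defaults here are typical
    natural-product spreads under which the mean differences are detectable
    at these sample sizes.
    """
    sds = {"mw": 130.0, "ob": 22.0, "caco2": 0.8, "dl": 0.15,
           "mlogp": 1.6, "tpsa": 45.0}
    return [
        HerbProfile(
            herb="ZHISHI",
            n_components=n_zhishi,
            means={"mw": 393.39, "ob": 28.94, "caco2": -0.20, "dl": 0.41,
                   "mlogp": 0.15, "nhacc": 7.67, "nhdon": 3.50, "tpsa": 51.65},
            sds=dict(sds),
            gi_high_prob=0.75,
        ),
        HerbProfile(
            herb="BAIZHU",
            n_components=n_baizhu,
            means={"mw": 252.67, "ob": 37.76, "caco2": 0.69, "dl": 0.20,
                   "mlogp": 2.10, "nhacc": 2.95, "nhdon": 1.54, "tpsa": 120.45},
            sds=dict(sds),
            gi_high_prob=0.9,
        ),
    ]


def gen_component_table(
    profiles: Sequence[HerbProfile], seed: int
) -> list[Component]:
    """Draw a synthetic component property table from per-herb profiles.

    Continuous properties come from normals clamped to their domains
    (DL to [0, 1], MW/OB/TPSA to >= 0); nHAcc/nHDon from Poissons at the
    profile means; the GI class is Bernoulli(gi_high_prob).
    """
    rng = np.random.default_rng(seed)
    components: list[Component] = []
    for profile in profiles:
        prefix = _ID_PREFIX.get(profile.herb, profile.herb[:2].upper())
        for i in range(profile.n_components):
            props: dict[str, float] = {}
            for prop, (lo, hi) in _CONTINUOUS.items():
                mean = profile.means[prop]
                sd = profile.sds.get(prop)
                if sd is None:
                    raise ValueError(f"no dispersion given for {prop!r}")
                v = float(rng.normal(mean, sd))
                if lo is not None:
                    v = max(v, lo)
                if hi is not None:
                    v = min(v, hi)
                props[prop] = v
            counts = {c: int(rng.poisson(profile.means[c])) for c in _COUNTS}
            gi = GIClass.HIGH if rng.random() < profile.gi_high_prob else GIClass.LOW
            components.append(
                Component(
                    id=f"{prefix}{i + 1}",
                    herb=profile.herb,
                    name=f"synthetic-{prefix}{i + 1}",
                    gi=gi,
                    **props,
                    **counts,
                )
            )
    return components


def gen_bipartite_edges(
    spec: NetworkSpec,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Generate a simple bipartite edge list with the requested edge count.

    Every component receives at least one target (degree >= 1); remaining
    edges are drawn uniformly without replacement from the unused
    component-target pairs. Returns ``(edges, herb_of)``.
    """
    rng = np.random.default_rng(spec.seed)
    comp_ids: list[str] = []
    herb_of: dict[str, str] = {}
    for herb in sorted(spec.n_components_by_herb):
        prefix = _ID_PREFIX.get(herb, herb[:2].upper())
        for i in range(spec.n_components_by_herb[herb]):
            cid = f"{prefix}{i + 1}"
            comp_ids.append(cid)
            herb_of[cid] = herb
    targets = [f"T{j + 1}" for j in range(spec.n_targets)]

    edges: set[tuple[str, str]] = set()
    for cid in comp_ids:
        edges.add((cid, targets[int(rng.integers(spec.n_targets))]))
    remaining = [
        (c, t) for c in comp_ids for t in targets if (c, t) not in edges
    ]
    extra = spec.n_edges - len(edges)
    if extra > 0:
        idx = rng.choice(len(remaining), size=extra, replace=False)
        edges.update(remaining[i] for i in idx)
    ordered = sorted(edges)
    assert len(ordered) == spec.n_edges
    return ordered, herb_of


def gen_annotation_universe(
    spec: PlantedEnrichmentSpec, query_set: Set[str]
) -> dict[str, set[str]]:
    """Annotation universe with one planted enriched annotation.

    The universe gene space is ``g1 .. gN``; ``query_set`` must be a subset
    of it. The planted annotation (``"planted"``) overlaps the query in
    exactly ``planted_overlap`` genes; decoy annotations (``"decoy_001"``
    etc.) are uniform draws from the universe.
    """
    universe = [f"g{i + 1}" for i in range(spec.universe_size)]
    uni_set = set(universe)
    if not set(query_set) <= uni_set:
        raise ValueError("query set must be a subset of the g1..gN universe")
    if spec.planted_overlap > len(query_set):
        raise ValueError("planted overlap exceeds query size")
    n_outside_needed = spec.planted_size - spec.planted_overlap
    outside = sorted(uni_set - set(query_set))
    if n_outside_needed > len(outside):
        raise ValueError("planted annotation does not fit outside the query set")

    rng = np.random.default_rng(spec.seed)
    query_sorted = sorted(query_set)
    in_query = rng.choice(len(query_sorted), size=spec.planted_overlap, replace=False)
    out_query = rng.choice(len(outside), size=n_outside_needed, replace=False)
    planted = {query_sorted[i] for i in in_query} | {outside[i] for i in out_query}

    annotations: dict[str, set[str]] = {"planted": planted}
    for d in range(spec.n_decoys):
        idx = rng.choice(spec.universe_size, size=spec.decoy_size, replace=False)
        annotations[f"decoy_{d + 1:03d}"] = {universe[i] for i in idx}
    # every universe gene appears in a catch-all so N equals universe_size
    annotations["background"] = uni_set
    return annotations


def gen_fingerprints(
    n: int, length: int = 61, density: float = 0.3, seed: int = 0
) -> list[Fingerprint]:
    """Independent Bernoulli(density) binary fingerprints, one per component."""
    if length < 1:
        raise ValueError("fingerprint length must be >= 1")
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    bits = (rng.random((n, length)) < density).astype(int)
    return [
        Fingerprint(component_id=f"C{i + 1}", bits=tuple(int(b) for b in row))
        for i, row in enumerate(bits)
    ]
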