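"""Domain types for multi-herb network-pharmacology analysis.

The core objects are the rows of the two input tables (herb components with
their ADME/physicochemical properties, and target proteins), binary
substructure fingerprints, and the bipartite networks built from
component->target and target->pathway edge lists.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "GIClass",
    "Component",
    "TargetProtein",
    "Fingerprint",
    "ScreeningCriteria",
    "ScreenDecision",
    "PropertyComparison",
    "NetworkSummary",
    "EnrichmentQuery",
    "EnrichmentResult",
    "ContributionResult",
    "HerbProfile",
    "NetworkSpec",
    "PlantedEnrichmentSpec",
]

#: Canonical herb labels for the two-herb formula; arbitrary labels are
#: accepted everywhere, these are just the defaults used by the fixtures
#: (ZS/BZ id prefixes).
ZHISHI = "ZHISHI"
BAIZHU = "BAIZHU"


class GIClass(enum.Enum):
    """Gastrointestinal absorption class (high/low)."""

    HIGH = "High"
    LOW = "Low"

    @classmethod
    def parse(cls, text: str) -> "GIClass":
        t = str(text).strip().lower()
        if t == "high":
            return cls.HIGH
        if t == "low":
            return cls.LOW
        raise ValueError(f"unrecognised GI absorption class: {text!r}")


@dataclass(frozen=True)
class Component:
    """One herb ingredient with its ADME / physicochemical properties.

    Attributes
    ----------
    id : str
        Short token, e.g. ``"ZS85"`` or ``"BZ27"``.
    herb : str
        Herb label (``"ZHISHI"`` / ``"BAIZHU"`` for the packaged tables).
    name : str
        Molecule name, free text.
    mw : float
        Molecular weight, g/mol.
    ob : float
        Oral bioavailability, percent (%F).
    caco2 : float
        Caco-2 permeability (log-scale, dimensionless).
    dl : float
        Drug-likeness, unitless in [0, 1].
    mlogp : float
        Moriguchi logP.
    nhacc, nhdon : int
        Hydrogen-bond acceptor / donor counts.
    tpsa : float
        Topological polar surface area, A^2.
    gi : GIClass
        Gastrointestinal absorption class.
    """

    id: str
    herb: str
    name: str
    mw: float
    ob: float
    caco2: float
    dl: float
    mlogp: float
    nhacc: int
    nhdon: int
    tpsa: float
    gi: GIClass

    def __post_init__(self) -> None:
        for attr in ("mw", "ob", "dl", "tpsa"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0 for {self.id}")
        for attr in ("nhacc", "nhdon"):
            v = getattr(self, attr)
            if v != int(v) or v < 0:
                raise ValueError(f"{attr} must be a non-negative integer for {self.id}")


@dataclass(frozen=True)
class TargetProtein:
    """A target protein: HGNC-style gene symbol, name, UniProt accession."""

    gene: str
    protein_name: str
    uniprot: str

    def __post_init__(self) -> None:
        if not self.uniprot:
            raise ValueError(f"empty UniProt accession for gene {self.gene}")


@dataclass(frozen=True)
class Fingerprint:
    """A binary chemical-substructure profile for one component."""

    component_id: str
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError(f"fingerprint bits must be 0/1 for {self.component_id}")


@dataclass(frozen=True)
class ScreeningCriteria:
    """The four-criterion ADME screen thresholds.

    Defaults follow the standard TCM screening practice: oral bioavailability
    at least 30%, Caco-2 permeability strictly above -0.4, drug-likeness at
    least 0.18 (relaxed to 0.14 for Baizhu, whose characteristic lactones
    fall between 0.14 and 0.18), and high GI absorption. ``whitelist``
    components are always retained regardless of the criteria (manual
    retentions of high-abundance, high-bioactivity ingredients).
    """

    ob_min: float = 30.0
    caco2_min_exclusive: float = -0.4
    dl_min_default: float = 0.18
    dl_min_by_herb: Mapping[str, float] = field(
        default_factory=lambda: {BAIZHU: 0.14}
    )
    gi_required: GIClass = GIClass.HIGH
    whitelist: frozenset[str] = frozenset()

    def dl_min(self, herb: str | None) -> float:
        if herb is not None and herb in self.dl_min_by_herb:
            return self.dl_min_by_herb[herb]
        return self.dl_min_default


@dataclass(frozen=True)
class ScreenDecision:
    """Outcome of screening one component."""

    component_id: str
    passed: bool
    failed_criteria: tuple[str, ...]
    retained_by_whitelist: bool = False

    def __post_init__(self) -> None:
        if self.passed and self.failed_criteria:
            raise ValueError("passed decision cannot carry failed criteria")

    @property
    def retained(self) -> bool:
        return self.passed or self.retained_by_whitelist


@dataclass(frozen=True)
class PropertyComparison:
    """Two-sample comparison of one molecular property across herbs."""

    property_name: str
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    n_a: int
    n_b: int


@dataclass(frozen=True)
class NetworkSummary:
    """Node/edge counts and mean degrees of a bipartite network."""

    n_left: int
    n_right: int
    n_edges: int

    @property
    def n_nodes(self) -> int:
        return self.n_left + self.n_right

    @property
    def mean_left_degree(self) -> float:
        return self.n_edges / self.n_left

    @property
    def mean_right_degree(self) -> float:
        return self.n_edges / self.n_right


@dataclass(frozen=True)
class EnrichmentQuery:
    """Hypergeometric over-representation query.

    N: universe size; K: annotated-set size; n: query-set size;
    k: overlap between query and annotated set.
    """

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("universe size N must be positive")
        if not (0 <= self.K <= self.N):
            raise ValueError("require 0 <= K <= N")
        if not (0 <= self.n <= self.N):
            raise ValueError("require 0 <= n <= N")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError("require 0 <= k <= min(n, K)")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-annotation over-representation result."""

    annotation_id: str
    query: EnrichmentQuery
    p: float
    significant: bool
    rank: int
    bh_p: float | None = None


@dataclass(frozen=True)
class ContributionResult:
    """Per-component contribution-score record.

    ``omega`` is the component's fraction of all edges in the merged
    component-target network; ``affinity`` the affinity index combining
    omega with the balance of the component's degree across the two herb
    subnetworks; ``cs`` the contribution score C_i * A_i * sum(P_j) over the
    component's targets; ``cs_pct`` its percentage of the total and
    ``cum_pct`` the running sum in rank order.
    """

    component_id: str
    herb: str
    degree: int
    degree_in_a: int
    degree_in_b: int
    omega: float
    affinity: float
    target_degree_sum: int
    cs: float
    cs_pct: float
    cum_pct: float
    rank: int


# ---------------------------------------------------------------------------
# Synthetic-data specifications


@dataclass(frozen=True)
class HerbProfile:
    """Per-herb property distributions for the synthetic component generator.

    Means/dispersions are per property; continuous properties are drawn from
    normals (clamped where the domain is bounded), integer counts from
    Poisson. ``gi_high_prob`` is the probability of the High GI class.
    """

    herb: str
    n_components: int
    means: Mapping[str, float]
    sds: Mapping[str, float]
    gi_high_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not (0.0 <= self.gi_high_prob <= 1.0):
            raise ValueError("gi_high_prob must be in [0, 1]")
        if any(s <= 0 for s in self.sds.values()):
            raise ValueError("dispersions must be > 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Spec for a synthetic two-herb bipartite component-target network."""

    n_components_by_herb: Mapping[str, int]
    n_targets: int
    n_edges: int
    seed: int

    @property
    def n_components(self) -> int:
        return sum(self.n_components_by_herb.values())

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_components < 1:
            raise ValueError("need at least one component and one target")
        if not (self.n_components <= self.n_edges <= self.n_components * self.n_targets):
            raise ValueError(
                f"n_edges={self.n_edges} infeasible for "
                f"{self.n_components} components x {self.n_targets} targets "
                "(every component needs degree >= 1)"
            )


@dataclass(frozen=True)
class PlantedEnrichmentSpec:
    """Spec for an annotation universe with one planted enriched annotation."""

    universe_size: int
    n_decoys: int
    planted_size: int
    planted_overlap: int
    decoy_size: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.planted_overlap <= self.planted_size <= self.universe_size):
            raise ValueError("require overlap <= planted size <= universe size")
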