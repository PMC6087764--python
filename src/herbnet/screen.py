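"""ADME screening, Tanimoto similarity, and per-herb property comparison.

The screen keeps components with oral bioavailability >= 30%, Caco-2
permeability > -0.4, drug-likeness >= 0.18 (herb-specific override 0.14 for
Baizhu) and high GI absorption; a whitelist retains named components that
fail the thresholds but are kept for high abundance / bioactivity.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .types import (
    Component,
    Fingerprint,
    PropertyComparison,
    ScreenDecision,
    ScreeningCriteria,
)

__all__ = [
    "tanimoto_drug_likeness",
    "binary_tanimoto",
    "evaluate_component",
    "apply_screen",
    "pairwise_similarity_summary",
    "compare_property",
]

#: Fixed reporting order for failed criteria.
CRITERIA_ORDER = ("OB", "CACO2", "DL", "GI")


def tanimoto_drug_likeness(a: Sequence[float], b: Sequence[float]) -> float:
    """Continuous Tanimoto coefficient T(A, B) = A.B / (|A|^2 + |B|^2 - A.B).

    Used for drug-likeness: A is a compound's molecular-descriptor vector
    and B a reference average drug vector. For non-negative vectors the
    result lies in [0, 1] and equals 1 iff A == B.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.shape != bv.shape or av.ndim != 1:
        raise ValueError(f"vector length mismatch: {av.shape} vs {bv.shape}")
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(bv))):
        raise ValueError("descriptor vectors must be finite")
    dot = float(av @ bv)
    denom = float(av @ av) + float(bv @ bv) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined for two all-zero vectors")
    return dot / denom


def binary_tanimoto(a: Fingerprint, b: Fingerprint, *, warn_empty: bool = True) -> float:
    """Jaccard/Tanimoto similarity |a AND b| / |a OR b| on binary fingerprints.

    A pair of all-zero fingerprints is counted as similarity 0 with a warning
    (no shared substructures to compare).
    """
    if len(a.bits) != len(b.bits):
        raise ValueError("fingerprint length mismatch")
    av = np.asarray(a.bits, dtype=bool)
    bv = np.asarray(b.bits, dtype=bool)
    union = int(np.sum(av | bv))
    if union == 0:
        if warn_empty:
            warnings.warn(
                f"both fingerprints empty for pair ({a.component_id}, {b.component_id}); "
                "similarity taken as 0",
                stacklevel=2,
            )
        return 0.0
    return int(np.sum(av & bv)) / union


def evaluate_component(c: Component, crit: ScreeningCriteria) -> ScreenDecision:
    """Apply the four ADME criteria to one component.

    OB and DL thresholds are inclusive; Caco-2 is strict; GI must equal the
    required class. Failed criteria are reported in the fixed order
    OB, CACO2, DL, GI.
    """
    failed: list[str] = []
    if not (c.ob >= crit.ob_min):
        failed.append("OB")
    if not (c.caco2 > crit.caco2_min_exclusive):
        failed.append("CACO2")
    if not (c.dl >= crit.dl_min(c.herb)):
        failed.append("DL")
    if c.gi != crit.gi_required:
        failed.append("GI")
    passed = not failed
    return ScreenDecision(
        component_id=c.id,
        passed=passed,
        failed_criteria=tuple(failed),
        retained_by_whitelist=(not passed) and c.id in crit.whitelist,
    )


def apply_screen(
    components: Sequence[Component], crit: ScreeningCriteria
) -> tuple[list[Component], list[ScreenDecision]]:
    """Screen a component table; return (retained components, all decisions).

    The retained set is the union of components passing all four criteria
    and whitelisted components present in the input, in input order.
    Whitelist ids absent from the input produce a warning, not an error.
    """
    decisions = [evaluate_component(c, crit) for c in components]
    present = {c.id for c in components}
    missing = set(crit.whitelist) - present
    if missing:
        warnings.warn(
            f"whitelist id(s) not in input table: {', '.join(sorted(missing))}",
            stacklevel=2,
        )
    active = [c for c, d in zip(components, decisions) if d.retained]
    return active, decisions


def pairwise_similarity_summary(
    fps: Sequence[Fingerprint], threshold: float = 0.2
) -> tuple[int, int, float]:
    """Profile all unordered fingerprint pairs against a similarity threshold.

    Returns ``(n_pairs, n_below_or_equal, fraction)`` where ``n_pairs`` is
    n(n-1)/2 and ``n_below_or_equal`` counts pairs with binary Tanimoto
    similarity <= threshold (dissimilar pairs, the drug-drug-interaction
    screen's "safe" fraction).
    """
    if len(fps) < 2:
        raise ValueError("need at least two fingerprints")
    n_pairs = 0
    n_le = 0
    for a, b in itertools.combinations(fps, 2):
        n_pairs += 1
        if binary_tanimoto(a, b) <= threshold:
            n_le += 1
    return n_pairs, n_le, n_le / n_pairs


def compare_property(
    values_a: Sequence[float],
    values_b: Sequence[float],
    property_name: str = "",
    *,
    welch: bool = False,
) -> PropertyComparison:
    """Two-sided two-sample Student's t-test (pooled variance by default).

    ``welch=True`` switches to Welch's unequal-variance test. Degenerate
    zero-variance input: equal means give t=0, p=1; unequal means with zero
    pooled variance are an error (the statistic is undefined).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("values must be finite")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
        else:
            raise ValueError("zero pooled variance with unequal means: t undefined")
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(t), float(p)
    return PropertyComparison(
        property_name=property_name,
        mean_a=mean_a,
        mean_b=mean_b,
        t_stat=t,
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
    )
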