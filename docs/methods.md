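# Methods

## The analysis model

`herbnet` treats a multi-herb formula as a layered system: herbs contribute
chemical components; components that survive a pharmacokinetic screen are
linked to protein targets; targets map to diseases and pathways. The package
implements the quantitative steps of that chain — screening, bipartite
network statistics, a per-component contribution score, and hypergeometric
over-representation — taking the upstream predictions (property values,
predicted component→target edges, annotation sets, fingerprints) as inputs.
It deliberately does not predict any of them itself: no oral-bioavailability
model, no target-prediction server, no database client. That keeps the
analysis reproducible from plain TSV files and makes every stage testable
against oracles.

## ADME screen

A component is retained when all four hold:

- OB ≥ `ob_min` (default 30 %) — inclusive, oral bioavailability as %F;
- Caco-2 > `caco2_min_exclusive` (default −0.4) — strict, log-scale
  monolayer permeability; values below −0.4 are conventionally read as
  "not permeable", so the boundary itself fails;
- DL ≥ herb-resolved threshold (default 0.18, with a per-herb override map
  defaulting to 0.14 for Baizhu, whose characteristic lactones sit between
  0.14 and 0.18) — inclusive;
- GI absorption equals the required class (default High).

Inclusivity follows the criteria's usual statement: the ≥ thresholds are
inclusive, the Caco-2 bound strict. A whitelist bypasses all four tests;
this models the common practice of retaining high-abundance, pharmacopoeia-
marker components that fail thresholds (on the packaged two-herb table,
exactly six components fail the defaults: BZ107, ZS104, ZS130, ZS143,
ZS144, ZS150). Failed criteria are reported in the fixed order OB, CACO2,
DL, GI so decision files diff cleanly.

Drug-likeness itself is consumed as an input column: the reference "average
drug" descriptor vector that defines it is not reconstructible from public
tables, so the continuous Tanimoto score
T(A,B) = A·B / (|A|² + |B|² − A·B) is exposed for users who supply their own
descriptor and reference vectors, while the screen reads the tabulated DL.

## Similarity profiling

Substructure fingerprints are fixed-length 0/1 vectors (default length 61,
configurable — published fingerprint dictionaries vary). Pairwise similarity
uses the binary Tanimoto |a∧b| / |a∨b| over all n(n−1)/2 unordered pairs;
the continuous formula is reserved for descriptor vectors. A pair of
all-zero fingerprints has no defined similarity; it is counted as 0 with a
warning rather than an error, since sparse fingerprint sets do occur.

## Property comparison

Between-herb property differences are tested with the two-sided two-sample
Student's t-test with pooled variance (`welch=True` switches to Welch).
Pooled Student's is the default because it is the test named in standard
screening workflows; with the group sizes involved (~130–150) the
distinction rarely matters. Zero pooled variance with equal means returns
t = 0, p = 1; with unequal means it is an error (the statistic is
undefined, and silently returning ±inf would poison downstream tables).

## Bipartite networks

Networks are simple (duplicate predicted interactions collapse to one
edge — degree figures then match what Cytoscape reports on an imported edge
list), undirected, strictly bipartite. Degrees are incident-edge counts;
declared isolated nodes keep degree 0. Mean degrees are kept at full
precision in the core; only report layers round to one decimal. Herb
subnetworks restrict edges to one herb's components and drop unreached
targets; when herb labels are total, the subnetwork edge sets partition the
merged network's edges, which is property-tested. Ranking ties are broken
by node id ascending for deterministic output.

## Contribution score

For component *i* in a merged two-herb C-T network with T edges:

- ω_i = C_i / T, its share of all edges (C_i its merged-network degree);
- A_i = ω_i + |(C_Ai + C_Bi) / (C_Ai − C_Bi)|, with C_Ai, C_Bi its degrees
  in the two herb subnetworks;
- CS(i) = C_i · A_i · Σ_j P_j, summing the merged-network degrees P_j of
  the component's own targets.

Design choices where the formula is genuinely open:

- The affinity index is a per-component constant (it carries no real
  dependence on the target index), applied to every incident target.
- The edge-weight ratio is read as (edges incident to component i) / (total
  edges of the merged network), consistent with its per-component indexing.
- Σ_j runs over the component's incident targets by default. The
  alternative reading — all targets in the network — would make the
  target-degree factor a global constant and reduce the ranking to
  C_i · A_i; it is available behind `sum_over="all"` rather than silently
  dismissed.
- When each component belongs to exactly one herb (disjoint ingredient
  sets, the usual two-herb case), one of C_Ai, C_Bi is zero, the ratio term
  is exactly 1, and A_i = ω_i + 1; this identity is property-tested.
- The degenerate balanced case C_Ai = C_Bi > 0 cannot arise with disjoint
  herbs but must be defined for shared components: the default `floor`
  policy floors the denominator at 1 (ratio term = C_Ai + C_Bi); `error`
  and `skip-term` are available.

Scores are reported as percentages of the total (they sum to 100 within
1e-9, enforced) and cumulatively in rank order (score descending, id
ascending). `cumulative_report` returns the smallest k reaching a cutoff
percentage. The reference per-component percentages for the Zhi-zhu Wan
network cannot be recomputed here because the underlying 650-edge list is
not publicly available; the package instead guarantees formula fidelity
through an
independent brute-force evaluator (raw edge-list loops, no shared code):
exhaustive agreement over *every* adjacency pattern and herb assignment up
to 3 components × 3 targets (~5,000 graphs), plus seeded random sweeps of
4×4 and 5×5 shapes. Exhausting all 5×5 adjacency matrices (2^25, times herb
assignments) is not tractable, so beyond 3×3 the sweep samples; the sampled
and exhaustive regimes exercise the same code path.

## Hypergeometric over-representation

The association between a query target set and an annotated set is the
upper tail P(X ≥ k) = 1 − Σ_{i<k} C(K,i)·C(N−K,n−i)/C(N,n). It is computed
in log space (log-gamma binomial coefficients, log-sum-exp over the
feasible upper tail) and clamped to [0, 1]; k = 0 returns exactly 1. The
implementation is verified against exact rational enumeration for all
N ≤ 30 (1e-12) and against an independent library survival function at
larger N. Ranking is by raw p ascending, then annotation id; significance
is flagged at α = 0.05 on the raw p, with a Benjamini–Hochberg column
included as good practice but not used for the primary flag — disease
rankings of this kind are conventionally reported on raw p, and fidelity to
that convention comes first. The universe size N defaults to the union of
annotated genes and can be overridden when the annotatable space is larger
(whether a curated resource's N counts genes or gene–disease pairs is a
choice the caller must make explicitly).

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, at the reference scale:

- **Component tables.** Two herb profiles with the reported per-herb
  property means (Zhishi-like: MW 393.39, OB 28.94, Caco-2 −0.20, DL 0.41,
  MLogP 0.15, nHAcc 7.67, nHDon 3.50, TPSA 51.65, n = 150; Baizhu-like:
  252.67, 37.76, 0.69, 0.20, 2.10, 2.95, 1.54, 120.45, n = 128). The TPSA
  means are taken at the face value of the reported figures even though the
  accompanying prose describes their direction inconsistently. Dispersions
  are not published; the defaults (MW 130, OB 22, Caco-2 0.8, DL 0.15,
  MLogP 1.6, TPSA 45) are typical natural-product spreads under which the
  planted mean differences are detectable (p < 0.01) at these sample sizes,
  chosen once and documented here. Continuous properties are clamped
  normals (DL to [0,1], MW/OB/TPSA to ≥ 0); nHAcc/nHDon are Poisson at the
  reported means; GI is Bernoulli.
- **Edge lists.** Exact requested edge count; every component is first
  given one uniform target (degree ≥ 1), then the remaining edges are drawn
  uniformly without replacement from unused pairs. This yields a
  near-binomial degree distribution — real predicted-target lists are more
  hub-dominated — so tests against these networks validate conservation
  laws and formula identities, not degree-distribution-dependent
  quantities.
- **Annotation universes.** A g1..gN gene space, one planted annotation
  overlapping the query in exactly k genes, uniform decoys, and a
  catch-all background annotation so the default universe size equals N.
- **Fingerprints.** Independent Bernoulli bits at a configurable density.

Every generator is a pure function of spec + seed (numpy `default_rng`);
reruns are bit-identical, which the tests assert. What passing synthetic
tests does **not** show: correctness of upstream property prediction or
target prediction, realistic correlation structure among properties (none
is modelled beyond per-herb means), or hub-dominated contribution-score
concentration.

## Pipeline

`run_pipeline` executes screen → C-T network (+ per-herb subnets and shared
targets) → contribution scores → optional T-P network, enrichment and
similarity stages, writing decisions.tsv, ct.sif/ct.graphml, cs.tsv,
enrichment.tsv and report.json. Herb labels come from the component table
where available and fall back to ZS/BZ id-prefix inference for edge-only
components. Failures raise a stage-named error and remove partial outputs.
The JSON report isolates the timestamp in a single field so two runs with
the same config and seed are otherwise identical, which is under test.

## Numerical and policy summary

| Choice | Default | Notes |
| --- | --- | --- |
| OB threshold | 30 % inclusive | screen |
| Caco-2 threshold | −0.4 strict | screen |
| DL threshold | 0.18 inclusive; per-herb map {BAIZHU: 0.14} | screen |
| GI class | High required | screen |
| Similarity threshold | 0.2 | pair profiling |
| Fingerprint length | 61 bits, configurable | published dictionaries vary |
| CS degenerate policy | floor (denominator ≥ 1) | `error`/`skip-term` available |
| CS target sum | incident targets | `all` behind a flag |
| Enrichment α | 0.05 on raw p | BH column provided |
| t-test | pooled Student's, two-sided | Welch behind a flag |
| Percent closure tolerance | 1e-9 | enforced invariant |

## Known limitations

- The contribution score is a topological heuristic: it weighs degree and
  herb balance, not binding affinity, expression or dose.
- Consumed DL/OB/Caco-2/GI values are only as good as their upstream
  predictors; the screen does not revalidate them.
- The per-herb property generator draws properties independently within a
  herb, so multivariate analyses (beyond per-property t-tests) should not
  be benchmarked against it.
- Enrichment assumes the query set is drawn from the same universe the
  annotations cover; mismatched namespaces (symbols vs accessions) are the
  caller's responsibility.
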