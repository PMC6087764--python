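# herbnet

Network-pharmacology analysis of multi-herb formulas, built around the
two-herb stomach-motility formula Zhi-zhu Wan (Zhishi, the immature fruit of
*Citrus aurantium*, plus Baizhu, the rhizome of *Atractylodes macrocephala*)
and its proposed action on functional dyspepsia. Herbal formulas act through
many components hitting many protein targets at once; this package provides
the quantitative scaffolding for that kind of analysis:

- **ADME screening** of component tables by four criteria — oral
  bioavailability OB ≥ 30 %, Caco-2 permeability > −0.4, drug-likeness
  DL ≥ 0.18 (herb-specific override, e.g. 0.14 for Baizhu lactones), and
  high GI absorption — plus a whitelist for manually retained components.
- **Bipartite networks**: component–target (C-T) and target–pathway (T-P)
  networks with degree statistics, per-herb subnetworks, shared-target sets,
  and Cytoscape-readable SIF/GraphML export.
- **Contribution scores**: for component *i* with degree *C_i* in a C-T
  network with *T* edges, ω_i = C_i / T, affinity
  A_i = ω_i + |(C_Ai + C_Bi)/(C_Ai − C_Bi)| over the two herb subnetworks,
  and CS(*i*) = C_i · A_i · Σ_j P_j summed over the degrees P_j of the
  component's targets; reported as percentages and cumulatively, so you can
  ask how many components carry, say, 90 % of the formula's predicted
  activity.
- **Over-representation analysis**: the hypergeometric upper tail
  P(X ≥ k) for the overlap k between a query target set (size n) and an
  annotated disease/pathway set (size K) in a universe of N targets, with
  optional Benjamini–Hochberg adjustment.
- **Similarity profiling**: binary Tanimoto |a∧b|/|a∨b| over all
  fingerprint pairs, and the continuous Tanimoto
  T(A,B) = A·B/(|A|² + |B|² − A·B) for descriptor vectors.
- **Synthetic data**: seeded generators for two-herb property tables,
  bipartite edge lists with exact edge counts, annotation universes with a
  planted enriched annotation, and binary fingerprints — every pipeline
  stage is testable without database access.

The reference 62-row Zhi-zhu Wan component table and 133-row target table
ship as packaged fixtures (`herbnet.load_zzw_components()`,
`herbnet.load_zzw_targets()`).

## Worked example

```python
import herbnet

components = herbnet.load_zzw_components()
active, decisions = herbnet.apply_screen(components, herbnet.ScreeningCriteria())
print(len(components), len(active),
      sorted(d.component_id for d in decisions if not d.passed))
```

prints

```
62 56 ['BZ107', 'ZS104', 'ZS130', 'ZS143', 'ZS144', 'ZS150']
```

i.e. of the 62 tabulated components, 56 pass all four thresholds and exactly
six fail — atractylone (BZ107), synephrine (ZS104), hesperidin (ZS130),
naringin (ZS143), narirutin (ZS144) and neohesperidin (ZS150), the
high-abundance components that a practitioner retains by whitelist:

```python
crit = herbnet.ScreeningCriteria(
    whitelist=frozenset({"BZ107", "ZS104", "ZS130", "ZS143", "ZS144", "ZS150"})
)
active, _ = herbnet.apply_screen(components, crit)
print(len(active))   # 62
```

A seeded synthetic C-T network at the reference scale, with its contribution
ranking:

```python
spec = herbnet.NetworkSpec(
    n_components_by_herb={"ZHISHI": 44, "BAIZHU": 17},
    n_targets=133, n_edges=650, seed=7,
)
edges, herb_of = herbnet.gen_bipartite_edges(spec)
net = herbnet.build_bipartite(edges, herb_of=herb_of)
s = herbnet.summarize(net)
print(s.n_nodes, round(s.mean_left_degree, 1), round(s.mean_right_degree, 1))
# 194 10.7 4.9

cs = herbnet.contribution_scores(net)
print(round(sum(r.cs_pct for r in cs), 6))     # 100.0
k, achieved = herbnet.cumulative_report(cs, 90.0)
print(k, round(achieved, 2))                    # 46 90.24
```

194 nodes is 61 components + 133 targets; each component reaches on average
10.7 targets and each target is reached by 4.9 components. The cumulative
scan says the top 46 of the 61 synthetic components carry 90.24 % of the
total contribution score (the concentration depends on the degree
distribution; real predicted-target lists are more hub-dominated).

The same operations are available from the shell:

```bash
herbnet screen --components components.tsv --out decisions.tsv
herbnet cs --edges ct_edges.tsv --herb-map herbs.tsv --out cs.tsv
herbnet enrich --targets query.txt --annotations annotations.tsv --out enr.tsv
herbnet simulate edges --seed 7 --out sim/
herbnet run --config run.yaml
```

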