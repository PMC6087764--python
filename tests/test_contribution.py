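"""Contribution-score formula fidelity, oracle equivalence, and ranking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet import (
    NetworkSpec,
    affinity_index,
    build_bipartite,
    contribution_scores,
    cumulative_report,
    edge_weight,
    gen_bipartite_edges,
)
from oracles import contribution_scores_naive

HERBS = ("ZHISHI", "BAIZHU")


def _net_from(edges, herb_of):
    return build_bipartite(edges, herb_of=herb_of)


class TestEdgeWeight:
    def test_printed_degree_fraction(self):
        # a degree-38 hub in a 650-edge network
        assert edge_weight(38, 650) == pytest.approx(38 / 650)

    def test_bounds(self):
        assert edge_weight(0, 10) == 0.0
        assert edge_weight(10, 10) == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            edge_weight(0, 0)


class TestAffinityIndex:
    def test_single_herb_ratio_is_one(self):
        assert affinity_index(0.05, 5, 0) == pytest.approx(1.05)

    def test_unbalanced(self):
        assert affinity_index(0.0, 3, 1) == pytest.approx(2.0)

    def test_degenerate_floor_policy(self):
        assert affinity_index(0.1, 2, 2) == pytest.approx(4.1)

    def test_degenerate_alternatives(self):
        assert affinity_index(0.1, 2, 2, policy="skip-term") == pytest.approx(0.1)
        with pytest.raises(ValueError, match="degenerate"):
            affinity_index(0.1, 2, 2, policy="error")

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError, match="no edges"):
            affinity_index(0.0, 0, 0)


class TestContributionScores:
    def test_single_component_hand_evaluation(self):
        net = _net_from([("c", "t")], {"c": "ZHISHI"})
        (r,) = contribution_scores(net, herbs=HERBS)
        assert r.omega == 1.0
        assert r.affinity == pytest.approx(2.0)  # omega 1 + ratio 1
        assert r.cs == pytest.approx(2.0)
        assert r.cs_pct == pytest.approx(100.0)
        assert r.rank == 1

    def test_symmetric_components_split_evenly(self):
        net = _net_from(
            [("c1", "t1"), ("c2", "t2")], {"c1": "ZHISHI", "c2": "ZHISHI"}
        )
        results = contribution_scores(net, herbs=HERBS)
        assert [r.cs_pct for r in results] == pytest.approx([50.0, 50.0])

    def test_disjoint_herbs_affinity_is_omega_plus_one(self, synthetic_ct_network):
        for r in contribution_scores(synthetic_ct_network, herbs=HERBS):
            assert r.affinity == pytest.approx(r.omega + 1.0, abs=1e-12)
            assert r.degree == r.degree_in_a + r.degree_in_b

    def test_cs_pct_sums_to_100(self, synthetic_ct_network):
        results = contribution_scores(synthetic_ct_network, herbs=HERBS)
        assert sum(r.cs_pct for r in results) == pytest.approx(100.0, abs=1e-9)
        cums = [r.cum_pct for r in results]
        assert all(b >= a - 1e-12 for a, b in zip(cums, cums[1:]))
        assert cums[-1] == pytest.approx(100.0, abs=1e-9)

    def test_exhaustive_small_graph_oracle_equivalence(self):
        """All adjacency patterns up to 3 components x 3 targets, every
        2-herb assignment, must match direct edge enumeration."""
        for n_c, n_t in [(1, 1), (1, 2), (2, 2), (2, 3), (3, 2), (3, 3)]:
            comps = [f"c{i}" for i in range(n_c)]
            targets = [f"t{j}" for j in range(n_t)]
            cells = [(c, t) for c in comps for t in targets]
            for mask in range(1, 2 ** len(cells)):
                edges = [cells[i] for i in range(len(cells)) if mask >> i & 1]
                present = sorted({a for a, _ in edges})
                for herb_mask in range(2 ** len(present)):
                    herb_of = {
                        c: HERBS[herb_mask >> i & 1] for i, c in enumerate(present)
                    }
                    expected = contribution_scores_naive(edges, herb_of, HERBS)
                    net = _net_from(edges, herb_of)
                    got = {
                        r.component_id: r.cs
                        for r in contribution_scores(net, herbs=HERBS)
                    }
                    assert got.keys() == expected.keys()
                    for c in expected:
                        assert got[c] == pytest.approx(expected[c], abs=1e-12), (
                            edges, herb_of, c,
                        )

    @pytest.mark.parametrize("shape", [(4, 4, 10), (5, 5, 14)])
    def test_random_larger_graphs_match_oracle(self, shape):
        n_c, n_t, n_e = shape
        rng = np.random.default_rng(12345)
        cells = [(f"c{i}", f"t{j}") for i in range(n_c) for j in range(n_t)]
        for _ in range(200):
            idx = rng.choice(len(cells), size=n_e, replace=False)
            edges = [cells[i] for i in idx]
            present = sorted({a for a, _ in edges})
            herb_of = {c: HERBS[int(rng.integers(2))] for c in present}
            expected = contribution_scores_naive(edges, herb_of, HERBS)
            net = _net_from(edges, herb_of)
            got = {r.component_id: r.cs for r in contribution_scores(net, herbs=HERBS)}
            for c in expected:
                assert got[c] == pytest.approx(expected[c], abs=1e-9)

    def test_cs_monotone_in_component_degree(self):
        # adding a target to c1 (target degrees held fixed by fresh targets)
        # must strictly increase its CS
        base = [("c1", "t1"), ("c1", "t2"), ("c2", "t3")]
        bigger = base + [("c1", "t4")]
        herb_of = {"c1": "ZHISHI", "c2": "BAIZHU"}
        cs_base = {
            r.component_id: r.cs
            for r in contribution_scores(_net_from(base, herb_of), herbs=HERBS)
        }
        cs_big = {
            r.component_id: r.cs
            for r in contribution_scores(_net_from(bigger, herb_of), herbs=HERBS)
        }
        assert cs_big["c1"] > cs_base["c1"]

    def test_planted_hub_attains_rank_one(self):
        """A component wired to every target (all of them high-degree)
        must outrank the background components."""
        spec = NetworkSpec(
            n_components_by_herb={"ZHISHI": 20, "BAIZHU": 10},
            n_targets=40,
            n_edges=120,
            seed=11,
        )
        edges, herb_of = gen_bipartite_edges(spec)
        hub = "HUB1"
        herb_of[hub] = "ZHISHI"
        edges = list(edges) + [(hub, f"T{j + 1}") for j in range(40)]
        net = _net_from(edges, herb_of)
        results = contribution_scores(net, herbs=HERBS)
        assert results[0].component_id == hub
        assert results[0].rank == 1

    def test_sum_over_all_targets_flag(self, synthetic_ct_network):
        results = contribution_scores(
            synthetic_ct_network, herbs=HERBS, sum_over="all"
        )
        total_deg = sum(
            synthetic_ct_network.degree[t] for t in synthetic_ct_network.right_nodes
        )
        assert all(r.target_degree_sum == total_deg for r in results)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_cs_pct_total_invariant_over_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n_c = int(rng.integers(2, 12))
        n_t = int(rng.integers(2, 15))
        max_e = n_c * n_t
        n_e = int(rng.integers(n_c, max_e + 1))
        spec = NetworkSpec(
            n_components_by_herb={"ZHISHI": n_c - n_c // 2, "BAIZHU": n_c // 2 or 1},
            n_targets=n_t,
            n_edges=min(n_e, (n_c - n_c // 2 + (n_c // 2 or 1)) * n_t),
            seed=seed % (2**31),
        )
        edges, herb_of = gen_bipartite_edges(spec)
        results = contribution_scores(_net_from(edges, herb_of), herbs=HERBS)
        assert sum(r.cs_pct for r in results) == pytest.approx(100.0, abs=1e-9)


class TestCumulativeReport:
    def test_equal_split(self):
        net = _net_from(
            [(f"c{i}", f"t{i}") for i in range(4)],
            {f"c{i}": "ZHISHI" for i in range(4)},
        )
        results = contribution_scores(net, herbs=HERBS)
        k, achieved = cumulative_report(results, 50.0)
        assert k == 2 and achieved == pytest.approx(50.0)

    def test_matches_brute_force_scan(self, synthetic_ct_network):
        results = contribution_scores(synthetic_ct_network, herbs=HERBS)
        for cutoff in (25.0, 49.49, 90.0, 100.0):
            k, achieved = cumulative_report(results, cutoff)
            running = list(itertools.accumulate(r.cs_pct for r in results))
            expected_k = next(
                i + 1 for i, v in enumerate(running) if v >= cutoff - 1e-12
            )
            assert k == expected_k
            assert achieved == pytest.approx(running[expected_k - 1])

    def test_invalid_cutoff(self, synthetic_ct_network):
        results = contribution_scores(synthetic_ct_network, herbs=HERBS)
        for bad in (0.0, -5.0, 120.0):
            with pytest.raises(ValueError):
                cumulative_report(results, bad)
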