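import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from circatf import (
    bipartite_edge_count,
    compare_correlation_sets,
    compare_path_lengths,
    fisher_enrichment,
    pearson_r,
    shortest_path_lengths,
    simulate_pathway_ppi,
    substrate_path_summary,
    top_k_correlated_mediators,
)
from circatf.networks import paired_t


class TestShortestPaths:
    def test_path_graph(self):
        g = nx.path_graph(["A", "B", "C"])
        lp = shortest_path_lengths(g, ["A"], ["C"]).set_index(["source", "target"])
        assert lp.loc[("A", "C"), "length"] == 2

    def test_self_distance_zero(self):
        g = nx.path_graph(["A", "B"])
        lp = shortest_path_lengths(g, ["A"], ["A"])
        assert lp.iloc[0].length == 0

    def test_unreachable_marked(self):
        g = nx.Graph([("A", "B"), ("C", "D")])
        lp = shortest_path_lengths(g, ["A"], ["D"])
        assert np.isnan(lp.iloc[0].length)

    def test_agrees_with_floyd_warshall_oracle(self):
        """scipy's dense Floyd-Warshall as an independent all-pairs oracle."""
        from scipy.sparse.csgraph import floyd_warshall

        rng = np.random.default_rng(6)
        g = nx.gnp_random_graph(25, 0.12, seed=42)
        adj = nx.to_numpy_array(g)
        dist = floyd_warshall(adj, unweighted=True)
        nodes = list(g.nodes)
        lp = shortest_path_lengths(g, nodes, nodes)
        for _, row in lp.iterrows():
            expect = dist[int(row.source), int(row.target)]
            if np.isinf(expect):
                assert np.isnan(row.length)
            else:
                assert row.length == expect

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            shortest_path_lengths(nx.path_graph(3), [], [0])


class TestComparePathLengths:
    def test_closed_form_example(self):
        """Differences (1,2,3): t = mean*sqrt(n)/sd = 2*sqrt(3)/1."""
        res = paired_t(np.array([1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(2 * math.sqrt(3), abs=1e-4)
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p_two_sided == pytest.approx(0.0742, abs=2e-4)

    def test_degenerate_all_zero_differences(self):
        ps = pd.DataFrame(
            {
                "mean_path_to_pathway_tfs": [2.0, 2.0, 2.0],
                "mean_path_to_all_tfs": [2.0, 2.0, 2.0],
            }
        )
        with pytest.raises(ValueError, match="degenerate|equal"):
            compare_path_lengths(ps)

    def test_planted_hub_topology_detected(self):
        """Pathway TFs adjacent to substrates yield shorter paths, p<0.05."""
        substrates = [f"S{i}" for i in range(15)]
        pw = [f"PTF{i}" for i in range(6)]
        other = [f"OTF{i}" for i in range(12)]
        g = simulate_pathway_ppi(substrates, pw, other, seed=3)
        ps = substrate_path_summary(g, substrates, pw, pw + other)
        res = compare_path_lengths(ps)
        assert (
            ps.mean_path_to_pathway_tfs.mean() < ps.mean_path_to_all_tfs.mean()
        )
        assert res.p_two_sided < 0.05


class TestTopKMediators:
    def _profiles(self, rows):
        return pd.DataFrame(rows).T

    def test_all_linked_when_k_covers(self):
        rng = np.random.default_rng(0)
        tf = self._profiles({"TF1": rng.normal(size=16)})
        meds = self._profiles({f"M{i}": rng.normal(size=16) for i in range(3)})
        out = top_k_correlated_mediators(tf, meds, k=3)
        assert len(out) == 3

    def test_identical_profile_ranks_first(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=16)
        tf = self._profiles({"TF1": x})
        meds = self._profiles({"M_same": x, "M_noise": rng.normal(size=16)})
        out = top_k_correlated_mediators(tf, meds, k=1)
        assert out.iloc[0].mediator_id == "M_same"
        assert out.iloc[0].r == pytest.approx(1.0)

    def test_tie_broken_lexicographically(self):
        x = np.arange(16.0)
        tf = self._profiles({"TF1": x})
        meds = self._profiles(
            {
                "M_b": 2 * x + 1,  # r = 1, ties with M_a
                "M_a": 3 * x,  # r = 1
                "M_c": -x,  # r = -1
            }
        )
        out = top_k_correlated_mediators(tf, meds, k=2)
        assert list(out.mediator_id) == ["M_a", "M_b"]

    def test_fewer_than_k_flagged(self):
        rng = np.random.default_rng(2)
        tf = self._profiles({"TF1": rng.normal(size=16)})
        meds = self._profiles({"M0": rng.normal(size=16)})
        out = top_k_correlated_mediators(tf, meds, k=3)
        assert len(out) == 1 and out.iloc[0].fewer_than_k


class TestCompareCorrelationSets:
    def _long(self, vals):
        return pd.DataFrame(
            [(f"TF{i}", f"M{i % 4}", r) for i, r in enumerate(vals)],
            columns=["tf_id", "mediator_id", "r"],
        )

    def test_clear_separation(self):
        rng = np.random.default_rng(3)
        pw = self._long(0.8 + 0.02 * rng.normal(size=12))
        al = self._long(0.2 + 0.02 * rng.normal(size=12))
        out = compare_correlation_sets(pw, al)
        assert out["mean_r_pathway"] - out["mean_r_all"] == pytest.approx(0.6, abs=0.05)
        assert out["p_two_sided"] < 0.01

    def test_identical_sets_statistic_zero(self):
        vals = self._long([0.1, 0.4, 0.3, 0.2, 0.5, 0.25, 0.15, 0.35])
        out = compare_correlation_sets(vals, vals.copy())
        assert out["t"] == 0.0 and out["p_two_sided"] == 1.0


class TestBipartiteEdges:
    def test_single_cross_edge(self):
        g = nx.Graph([("A", "B")])
        assert bipartite_edge_count({"A"}, {"B"}, g) == 1

    def test_within_set_edge_excluded(self):
        g = nx.Graph([("A", "A2")])
        assert bipartite_edge_count({"A", "A2"}, {"B"}, g) == 0

    def test_complete_graph_cross_count(self):
        g = nx.complete_graph(["A", "B", "C", "D"])
        assert bipartite_edge_count({"A", "B"}, {"C", "D"}, g) == 4

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(20, 0.3, seed=7)
        a = set(rng.choice(20, 8, replace=False).tolist())
        b = set(rng.choice(20, 8, replace=False).tolist())
        assert bipartite_edge_count(a, b, g) == bipartite_edge_count(b, a, g)


class TestFisherEnrichment:
    def test_exact_tail_oracle(self):
        """p equals the explicit binomial-coefficient tail sum."""
        bg = [f"g{i}" for i in range(60)]
        fg = bg[:10]
        sets = {"S": bg[5:15]}  # overlap with fg = 5, set size 10
        out = fisher_enrichment(fg, bg, sets)
        expect = sum(
            math.comb(10, k) * math.comb(50, 10 - k) for k in range(5, 11)
        ) / math.comb(60, 10)
        assert out.iloc[0].p == pytest.approx(expect, rel=1e-12)

    def test_fg_equals_bg_no_enrichment(self):
        bg = [f"g{i}" for i in range(30)]
        out = fisher_enrichment(bg, bg, {"S": bg[:7]})
        assert out.iloc[0].p == pytest.approx(1.0)

    def test_disjoint_set_near_one(self):
        bg = [f"g{i}" for i in range(100)]
        out = fisher_enrichment(bg[:10], bg, {"S": bg[90:93]})
        assert out.iloc[0].p > 0.5

    def test_empty_fg_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment([], ["a"], {"S": ["a"]})


class TestPearsonR:
    def test_identity(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_affine_negative(self):
        x = np.arange(10.0)
        assert pearson_r(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_hand_computed(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])
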