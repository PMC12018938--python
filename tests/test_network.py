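"""Correlation networks: Spearman matrices, edge filters, clustering,
pi0 size estimation, subsampling, identity-line summaries."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from immunoprofile import (
    cluster_edge_betweenness,
    estimate_pi0,
    estimate_unrestricted_size,
    identity_line_summary,
    n_pairs,
    spearman_matrix,
    subsample_comparison,
)
from immunoprofile.network import (
    build_restricted_network,
    exact_spearman_pvalue,
    network_statistic,
    pct_below_identity,
)


class TestNPairs:
    @pytest.mark.parametrize("m,expected", [(56, 1540), (2, 1), (10, 45)])
    def test_values(self, m, expected):
        assert n_pairs(m) == expected

    def test_too_few_raises(self):
        with pytest.raises(ValueError):
            n_pairs(1)


class TestSpearman:
    def test_reversal_exact_p(self):
        x = np.arange(5.0)
        rho, p = exact_spearman_pvalue(x, x[::-1])
        assert rho == pytest.approx(-1.0)
        assert p == pytest.approx(2 / 120)

    def test_exact_matches_enumeration_for_moderate_rho(self, rng):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 1.7])
        from scipy.stats import rankdata, spearmanr

        rho_obs = spearmanr(x, y).statistic
        rx, ry = rankdata(x), rankdata(y)
        denom = 6 * (6 * 6 - 1) / 6
        count = sum(
            abs(1 - np.sum((np.array(p) - rx) ** 2) / denom) >= abs(rho_obs) - 1e-12
            for p in itertools.permutations(ry)
        )
        rho, p = exact_spearman_pvalue(x, y)
        assert p == pytest.approx(count / 720)

    def test_monotone_pair(self, rng):
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": np.exp(x), "c": rng.normal(size=30)})
        rho, p = spearman_matrix(df)
        assert rho.loc["a", "b"] == pytest.approx(1.0)
        assert p.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(p.loc["a", "a"])  # self-pairs excluded

    def test_constant_marker_flagged_undefined(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        rho, p = spearman_matrix(df)
        assert np.isnan(rho.loc["a", "b"]) and np.isnan(p.loc["a", "b"])


class TestRestrictedNetwork:
    def _fixture(self):
        markers = list("abcde")
        rho = pd.DataFrame(np.eye(5), index=markers, columns=markers)
        p = pd.DataFrame(np.ones((5, 5)), index=markers, columns=markers)

        def put(i, j, r, pv):
            rho.iloc[i, j] = rho.iloc[j, i] = r
            p.iloc[i, j] = p.iloc[j, i] = pv

        # three pairs pass both filters
        put(0, 1, 0.9, 1e-8)
        put(0, 2, 0.8, 1e-8)
        put(1, 2, -0.85, 1e-8)
        # strong rho, weak p: fails FDR filter
        put(3, 4, 0.95, 0.9)
        # strong p, weak rho: fails the magnitude filter
        put(2, 3, 0.5, 1e-8)
        np.fill_diagonal(p.values, np.nan)
        return rho, p

    def test_mixed_fixture_size_three(self):
        rho, p = self._fixture()
        net = build_restricted_network(rho, p, cluster=False)
        assert net.restricted_size == 3
        assert net.average_degree == pytest.approx(6 / 5)

    def test_saturated_and_empty(self, rng):
        m = 6
        markers = [f"m{i}" for i in range(m)]
        ones = pd.DataFrame(0.99 * np.ones((m, m)), index=markers, columns=markers)
        tiny = pd.DataFrame(np.full((m, m), 1e-10), index=markers, columns=markers)
        np.fill_diagonal(tiny.values, np.nan)
        net = build_restricted_network(ones, tiny, cluster=False)
        assert net.restricted_size == n_pairs(m)
        half = pd.DataFrame(0.5 * np.ones((m, m)), index=markers, columns=markers)
        assert build_restricted_network(half, tiny, cluster=False).restricted_size == 0

    def test_monotone_in_thresholds(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 8)))
        df.iloc[:, 1] = df.iloc[:, 0] * 0.9 + rng.normal(scale=0.3, size=40)
        df.iloc[:, 3] = df.iloc[:, 2] * 0.8 + rng.normal(scale=0.5, size=40)
        rho, p = spearman_matrix(df)
        sizes = [
            build_restricted_network(rho, p, fdr=f, rho_min=r, cluster=False
                                     ).restricted_size
            for f, r in [(0.10, 0.5), (0.10, 0.7), (0.05, 0.7)]
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestClustering:
    def test_two_cliques_plus_singleton(self):
        g = nx.Graph()
        g.add_nodes_from(range(9))
        for clique in ([0, 1, 2, 3], [4, 5, 6, 7]):
            g.add_edges_from(itertools.combinations(clique, 2))
        parts = cluster_edge_betweenness(g)
        assert frozenset([0, 1, 2, 3]) in parts
        assert frozenset([4, 5, 6, 7]) in parts
        assert frozenset([8]) in parts

    def test_empty_graph_all_singletons(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        assert sorted(cluster_edge_betweenness(g)) == [
            frozenset("a"), frozenset("b"), frozenset("c")
        ]

    def test_barbell_bridge_has_max_brute_force_betweenness(self):
        g = nx.Graph()
        for clique in ([0, 1, 2, 3], [4, 5, 6, 7]):
            g.add_edges_from(itertools.combinations(clique, 2))
        g.add_edge(3, 4)
        # brute force: count shortest paths through each edge over all pairs
        counts = {tuple(sorted(e)): 0.0 for e in g.edges}
        for s, t in itertools.combinations(g.nodes, 2):
            paths = list(nx.all_shortest_paths(g, s, t))
            for path in paths:
                for e in zip(path, path[1:]):
                    counts[tuple(sorted(e))] += 1.0 / len(paths)
        assert max(counts, key=counts.get) == (3, 4)
        nx_bet = nx.edge_betweenness_centrality(g, normalized=False)
        for e, v in counts.items():
            assert nx_bet[e] == pytest.approx(v)
        parts = cluster_edge_betweenness(g)
        assert frozenset([0, 1, 2, 3]) in parts and frozenset([4, 5, 6, 7]) in parts


class TestPi0:
    def test_saturated_signal(self):
        p = np.full(1540, 1e-12)
        pi0, size, avg = estimate_unrestricted_size(p, 56)
        assert pi0 == pytest.approx(0.0, abs=0.02)
        assert size == pytest.approx(1540, abs=40)
        assert avg == pytest.approx(55, abs=2)

    def test_table_rounding_convention(self):
        assert round(2 * 949 / 56) == 34
        assert round(2 * 147 / 56) == 5

    def test_uniform_null(self, rng):
        pi0s = [estimate_pi0(rng.random(1540)) for _ in range(20)]
        assert np.mean(pi0s) == pytest.approx(1.0, abs=0.05)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            estimate_pi0([])

    def test_fixed_lambda_variant(self, rng):
        p = rng.random(2000)
        pi0 = estimate_pi0(p, method="fixed")
        assert pi0 == pytest.approx(1.0, abs=0.08)


class TestSubsampling:
    def test_deterministic(self, rng):
        pwoh = pd.DataFrame(rng.normal(size=(40, 6)))
        plwh = pd.DataFrame(rng.normal(size=(15, 6)))
        a = subsample_comparison(pwoh, plwh, R=30, seed=5)
        b = subsample_comparison(pwoh, plwh, R=30, seed=5)
        assert np.allclose(a.values, b.values)
        assert a.prob_pwoh_gt_plwh == b.prob_pwoh_gt_plwh

    def test_prob_one_when_reference_below_everything(self, rng):
        base = rng.normal(size=(60, 6))
        pwoh = pd.DataFrame(base)
        pwoh.iloc[:, 1] = pwoh.iloc[:, 0] + rng.normal(scale=0.05, size=60)
        pwoh.iloc[:, 3] = pwoh.iloc[:, 2] + rng.normal(scale=0.05, size=60)
        plwh = pd.DataFrame(rng.normal(size=(20, 6)))  # no correlated pairs
        out = subsample_comparison(pwoh, plwh, R=25, seed=3)
        assert out.reference_value == 0
        assert out.prob_pwoh_gt_plwh == 1.0

    def test_summary_consistent_with_values(self, rng):
        pwoh = pd.DataFrame(rng.normal(size=(40, 5)))
        plwh = pd.DataFrame(rng.normal(size=(12, 5)))
        out = subsample_comparison(pwoh, plwh, R=20, seed=1)
        s = out.summary()
        assert s["mean"] == pytest.approx(out.values.mean())
        assert s["n_subsamples"] == 20

    def test_pwoh_smaller_raises(self, rng):
        with pytest.raises(ValueError):
            subsample_comparison(pd.DataFrame(rng.normal(size=(5, 4))),
                                 pd.DataFrame(rng.normal(size=(10, 4))))


class TestIdentityLine:
    def test_printed_percent_convention(self):
        assert pct_below_identity(1009, 1540) == 65.5
        assert pct_below_identity(1072, 1540) == 69.6

    def test_identical_matrices(self, rng):
        m = pd.DataFrame(np.eye(4), columns=list("abcd"), index=list("abcd"))
        out = identity_line_summary(m, m)
        assert out["n_below"] == 0 and out["pct_below"] == 0.0

    def test_counts_strictly_below(self):
        markers = list("abc")
        a = pd.DataFrame([[1, 0.5, 0.2], [0.5, 1, 0.4], [0.2, 0.4, 1]],
                         index=markers, columns=markers)
        b = pd.DataFrame([[1, 0.3, 0.2], [0.3, 1, 0.6], [0.2, 0.6, 1]],
                         index=markers, columns=markers)
        out = identity_line_summary(a, b)
        assert out["n_pairs"] == 3
        assert out["n_below"] == 1  # only the (a,b) pair decreased

    def test_mismatched_markers_raise(self, rng):
        a = pd.DataFrame(np.eye(3), columns=list("abc"), index=list("abc"))
        b = pd.DataFrame(np.eye(3), columns=list("abd"), index=list("abd"))
        with pytest.raises(ValueError):
            identity_line_summary(a, b)
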