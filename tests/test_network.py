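"""Trait network construction, metrics and the focal-trait comparison.

Betweenness and average path length are validated against exhaustive
enumeration of all simple paths on every test graph with <= 8 nodes.
"""

import itertools

import numpy as np
import pytest

import rhizonet as rz
from rhizonet import TraitCorrelations


def make_corr(names, pairs):
    """TraitCorrelations from {(a, b): (r, p)} entries."""
    p = len(names)
    r = np.eye(p)
    pv = np.ones((p, p))
    for (a, b), (rv, pval) in pairs.items():
        i, j = names.index(a), names.index(b)
        r[i, j] = r[j, i] = rv
        pv[i, j] = pv[j, i] = pval
    return TraitCorrelations(names=tuple(names), mean=np.zeros(p),
                             rate=r.copy(), corr=r, pvalues=pv, n=32)


def brute_force_paths(A, tol=1e-12):
    """All-pairs shortest-path costs and normalized betweenness by
    exhaustive enumeration of simple paths (additive edge cost A[i, j])."""
    n = A.shape[0]
    best = {}
    for s, t in itertools.combinations(range(n), 2):
        paths = []
        for k in range(n - 1):
            for mid in itertools.permutations(
                    [v for v in range(n) if v not in (s, t)], k):
                seq = (s, *mid, t)
                if all(A[a, b] > 0 for a, b in zip(seq, seq[1:])):
                    paths.append((sum(A[a, b] for a, b in zip(seq, seq[1:])),
                                  seq))
        if paths:
            dmin = min(c for c, _ in paths)
            best[(s, t)] = (dmin, [q for c, q in paths if c <= dmin + tol])
    bet = np.zeros(n)
    for v in range(n):
        for (s, t), (dmin, shortest) in best.items():
            if v in (s, t):
                continue
            through = sum(1 for q in shortest if v in q)
            bet[v] += through / len(shortest)
    norm = (n - 1) * (n - 2) / 2
    dists = [d for d, _ in best.values()]
    connected = len(best) == n * (n - 1) // 2
    apl = np.mean(dists) if connected else np.nan
    return apl, bet / norm, connected


class TestBuildNetwork:
    def test_published_matrix_edge_count_and_focal_degree(self, table1):
        net = rz.build_network(table1)
        assert net.n_edges == 18
        s = rz.single_trait_metrics(net)
        assert s.degree[s.names.index("colM")] == 6

    def test_threshold_one_not_allowed_but_high_threshold_empties(self, table1):
        with pytest.raises(ValueError):
            rz.build_network(table1, threshold=1.0)
        net = rz.build_network(table1, threshold=0.99)
        assert net.n_edges == 0
        s = rz.network_summary(net)
        assert np.all(s.degree == 0) and np.isnan(s.average_path_length)

    def test_complete_graph_when_everything_passes(self):
        names = list("wxyz")
        corr = make_corr(names, {(a, b): (0.9, 0.001)
                                 for a, b in itertools.combinations(names, 2)})
        net = rz.build_network(corr)
        assert net.n_edges == 6

    def test_both_rules_required(self):
        corr = make_corr(["a", "b", "c"],
                         {("a", "b"): (0.9, 0.5),    # strong but not significant
                          ("a", "c"): (0.3, 0.001),  # significant but weak
                          ("b", "c"): (0.7, 0.01)})
        net = rz.build_network(corr)
        assert list(net.edges()) == [("b", "c", 0.7, 1)]

    def test_signs_recorded(self, table1):
        net = rz.build_network(table1)
        edges = {(a, b): s for a, b, _, s in net.edges()}
        assert edges[("colM", "RD")] == 1
        assert edges[("colM", "RTD")] == -1


class TestExcludeTrait:
    def test_removing_colm_leaves_twelve_edges(self, table1):
        net = rz.build_network(rz.exclude_trait(table1, "colM"))
        assert net.n_edges == 12

    def test_entries_unchanged(self, table1):
        sub = rz.exclude_trait(table1, "RCC")
        for a in sub.names:
            for b in sub.names:
                i, j = sub.names.index(a), sub.names.index(b)
                oi, oj = table1.names.index(a), table1.names.index(b)
                assert sub.corr[i, j] == table1.corr[oi, oj]

    def test_unknown_trait_rejected(self, table1):
        with pytest.raises(KeyError):
            rz.exclude_trait(table1, "nope")

    def test_exclusion_commutes_with_building(self, table1):
        # dropping then building == building then deleting the node
        net_a = rz.build_network(rz.exclude_trait(table1, "colM"))
        net_b = rz.build_network(table1)
        idx = [i for i, t in enumerate(net_b.names) if t != "colM"]
        sub = net_b.adjacency[np.ix_(idx, idx)]
        np.testing.assert_array_equal(net_a.adjacency, sub)


class TestMetrics:
    def test_path_graph_betweenness(self):
        corr = make_corr(["A", "B", "C"], {("A", "B"): (0.6, 0.01),
                                           ("B", "C"): (0.6, 0.01)})
        s = rz.single_trait_metrics(rz.build_network(corr))
        np.testing.assert_array_equal(s.degree, [1, 2, 1])
        np.testing.assert_allclose(s.betweenness, [0, 1.0, 0])

    def test_triangle_unit_weights_cannot_exist_but_high_weights(self):
        corr = make_corr(["a", "b", "c"],
                         {p: (0.99, 0.001) for p in
                          itertools.combinations("abc", 2)})
        s = rz.network_summary(rz.build_network(corr))
        assert s.edge_density == 1.0
        assert s.clustering == 1.0
        assert s.average_path_length == pytest.approx(0.99)

    def test_degree_additivity(self, table1):
        net = rz.build_network(table1)
        s = rz.single_trait_metrics(net)
        assert s.degree.sum() == 2 * net.n_edges
        assert s.weighted_degree.sum() == pytest.approx(
            2 * net.adjacency.sum() / 2)

    def test_hub_trait_is_max_weighted_degree(self, table1):
        s = rz.network_summary(rz.build_network(table1))
        i = int(np.argmax(s.weighted_degree))
        assert s.names[i] in s.hub_traits

    def test_isolated_node_leaves_others_unchanged(self):
        base = {("a", "b"): (0.8, 0.01), ("b", "c"): (0.7, 0.01),
                ("a", "c"): (0.6, 0.01)}
        s3 = rz.single_trait_metrics(rz.build_network(
            make_corr(["a", "b", "c"], base)))
        s4 = rz.single_trait_metrics(rz.build_network(
            make_corr(["a", "b", "c", "iso"], base)))
        for t in "abc":
            i3, i4 = s3.names.index(t), s4.names.index(t)
            assert s3.degree[i3] == s4.degree[i4]
            assert s3.weighted_degree[i3] == pytest.approx(
                s4.weighted_degree[i4])

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        names = [f"t{i}" for i in range(n)]
        pairs = {}
        for a, b in itertools.combinations(names, 2):
            if rng.random() < 0.45:
                pairs[(a, b)] = (float(rng.uniform(0.51, 0.99)), 0.01)
        corr = make_corr(names, pairs)
        net = rz.build_network(corr)
        s = rz.single_trait_metrics(net)
        apl, bet, connected = brute_force_paths(net.adjacency)
        np.testing.assert_allclose(s.betweenness, bet, atol=1e-10)
        assert s.connected == connected
        if connected:
            assert s.average_path_length == pytest.approx(apl)
        else:
            assert np.isnan(s.average_path_length)


class TestPairedT:
    def test_printed_degree_rows(self, table3):
        a = table3["with_focal"]["degree"][1:]      # shared traits only
        b = table3["without_focal"]["degree"]
        t, df, p = rz.paired_t_test(a, b)
        assert t == pytest.approx(4.58, abs=0.005)
        assert df == 7
        assert p == pytest.approx(0.003, abs=5e-4)

    def test_identical_vectors(self):
        t, df, p = rz.paired_t_test([1, 2, 3], [1, 2, 3])
        assert (t, df, p) == (0.0, 2, 1.0)

    def test_hand_computed_differences(self):
        b = np.zeros(8)
        a = np.array([0.8, 0.7, 0.5, 0, 0.5, 0.5, 0, 0.6])
        t, df, p = rz.paired_t_test(a, b)
        assert t == pytest.approx(0.45 / (a.std(ddof=1) / np.sqrt(8)))
        assert t == pytest.approx(4.28, abs=0.01)

    def test_degenerate_nonzero_differences(self):
        with pytest.raises(ValueError, match="degenerate"):
            rz.paired_t_test([1, 2, 3], [0, 1, 2])


class TestCompareNetworks:
    def test_degree_t_statistic_matches_published(self, table1):
        cmp_ = rz.compare_networks(table1, "colM")
        t, df, p = cmp_.tests["degree"]
        assert t == pytest.approx(4.58, abs=0.005)
        assert df == 7

    def test_focal_without_edges_gives_zero_t(self):
        names = ["f", "a", "b", "c"]
        corr = make_corr(names, {("a", "b"): (0.8, 0.01),
                                 ("b", "c"): (0.7, 0.01),
                                 ("a", "c"): (0.9, 0.01)})
        cmp_ = rz.compare_networks(corr, "f")
        assert cmp_.tests["degree"][0] == 0.0
        assert cmp_.tests["degree"][2] == 1.0

    def test_matches_manual_two_network_computation(self, table1):
        cmp_ = rz.compare_networks(table1, "colM")
        s_with = rz.single_trait_metrics(rz.build_network(table1))
        s_wo = rz.single_trait_metrics(
            rz.build_network(rz.exclude_trait(table1, "colM")))
        shared = [t for t in table1.names if t != "colM"]
        a = [s_with.weighted_degree[s_with.names.index(t)] for t in shared]
        b = [s_wo.weighted_degree[s_wo.names.index(t)] for t in shared]
        t_manual, df, p = rz.paired_t_test(a, b)
        assert cmp_.tests["weighted_degree"][0] == pytest.approx(t_manual)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_matrices_compositional(self, seed):
        rng = np.random.default_rng(100 + seed)
        names = [f"t{i}" for i in range(6)]
        pairs = {}
        for a, b in itertools.combinations(names, 2):
            pairs[(a, b)] = (float(rng.uniform(-0.95, 0.95)),
                             float(rng.choice([0.01, 0.2])))
        corr = make_corr(names, pairs)
        focal = names[0]
        cmp_ = rz.compare_networks(corr, focal)
        s_with = rz.single_trait_metrics(rz.build_network(corr))
        s_wo = rz.single_trait_metrics(
            rz.build_network(rz.exclude_trait(corr, focal)))
        shared = names[1:]
        for metric in ("degree", "weighted_degree", "betweenness"):
            va = [getattr(s_with, metric)[s_with.names.index(t)]
                  for t in shared]
            vb = [getattr(s_wo, metric)[s_wo.names.index(t)] for t in shared]
            d = np.asarray(va, float) - np.asarray(vb, float)
            if d.std(ddof=1) == 0:
                continue
            t_manual, _, _ = rz.paired_t_test(va, vb)
            assert cmp_.tests[metric][0] == pytest.approx(t_manual)
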