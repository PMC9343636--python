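import itertools
import math
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import seedtrans as st
from seedtrans.io import DataError
from seedtrans.networks import AssocNetwork, MetaNetwork


def _net_from_edges(edges, context=("all", "all"), signs=None):
    g = nx.Graph()
    for i, (u, v) in enumerate(edges):
        sign = signs[i] if signs else "pos"
        g.add_edge(u, v, rho=0.5 if sign == "pos" else -0.5, q=0.01, sign=sign)
    return AssocNetwork(graph=g, context=context)


class TestSparcc:
    def test_closed_form_basis_for_three_taxa(self):
        t_mat = np.array([[0.0, 2.0, 2.0], [2.0, 0.0, 2.0], [2.0, 2.0, 0.0]])
        rho, omega, flagged = st.basis_correlations(t_mat)
        assert np.allclose(omega, 1.0, atol=1e-10)
        off = rho[np.triu_indices(3, 1)]
        assert np.allclose(off, 0.0, atol=1e-10)

    def test_general_solver_matches_closed_form_d3(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.uniform(0.5, 2.0, 3)
            t_mat = np.zeros((3, 3))
            pairs = [(0, 1), (0, 2), (1, 2)]
            for (a, b), val in zip(pairs, v):
                t_mat[a, b] = t_mat[b, a] = val
            rho, omega, _ = st.basis_correlations(t_mat, exclusion_thresh=2.0)
            t_ab, t_ac, t_bc = t_mat[0, 1], t_mat[0, 2], t_mat[1, 2]
            expected0 = (t_ab + t_ac - t_bc) / 2
            assert omega[0] == pytest.approx(expected0, abs=1e-10)

    def test_planted_correlation_recovered(self):
        corr = np.eye(50)
        corr[0, 1] = corr[1, 0] = 0.8
        t, _ = st.simulate_correlated_counts(50, 200, corr, depth=10000, seed=2)
        rho = st.sparcc(t, seed=3)
        assert 0.65 <= rho.iloc[0, 1] <= 0.95
        null = rho.to_numpy()[np.triu_indices(50, 1)]
        null = np.delete(null, 0)  # drop the planted pair
        assert float(np.sqrt((null ** 2).mean())) < 0.1

    def test_sample_order_invariance(self):
        # the deterministic core (variation matrix -> basis solve) is
        # exactly invariant to sample order
        rng = np.random.default_rng(4)
        fracs = rng.dirichlet(np.ones(10), size=40).T  # taxa x samples
        rho_a, _, _ = st.basis_correlations(st.variation_matrix(fracs))
        perm = rng.permutation(40)
        rho_b, _, _ = st.basis_correlations(st.variation_matrix(fracs[:, perm]))
        assert np.allclose(rho_a, rho_b, atol=1e-12)

    def test_pvalues_symmetric_and_floor_for_planted_pair(self):
        corr = np.eye(15)
        corr[0, 1] = corr[1, 0] = 0.99
        t, _ = st.simulate_correlated_counts(15, 60, corr, depth=5000, seed=6)
        rho = st.sparcc(t, n_resample=8, seed=7)
        p, q = st.sparcc_pvalues(t, rho, n_perm=40, seed=8, n_resample=4)
        arr = p.to_numpy()
        assert np.allclose(arr, arr.T)
        assert p.iloc[0, 1] == pytest.approx(1 / 41)

    def test_null_rejection_rate_near_alpha(self):
        t, _ = st.simulate_correlated_counts(20, 60, None, depth=5000, seed=9)
        rho = st.sparcc(t, n_resample=8, seed=10)
        p, _ = st.sparcc_pvalues(t, rho, n_perm=60, seed=11, n_resample=4)
        pv = p.to_numpy()[np.triu_indices(20, 1)]
        assert abs(float((pv <= 0.05).mean()) - 0.05) <= 0.08


class TestBuildNetwork:
    def _mats(self, rho_val, q_val):
        ids = ["a", "b", "c", "d"]
        rho = pd.DataFrame(np.eye(4), index=ids, columns=ids)
        q = pd.DataFrame(np.ones((4, 4)), index=ids, columns=ids)
        rho.loc["a", "b"] = rho.loc["b", "a"] = rho_val
        q.loc["a", "b"] = q.loc["b", "a"] = q_val
        return rho, q

    def test_coefficient_exactly_at_threshold_excluded(self):
        rho, q = self._mats(0.3, 0.01)
        net = st.build_network(rho, q)
        assert net.n_edges == 0

    def test_negative_edge_retained_with_sign(self):
        rho, q = self._mats(-0.31, 0.04)
        net = st.build_network(rho, q)
        assert net.n_edges == 1
        assert net.graph["a"]["b"]["sign"] == "neg"

    def test_permissive_thresholds_give_complete_graph(self):
        rng = np.random.default_rng(1)
        ids = [f"o{i}" for i in range(6)]
        arr = rng.uniform(0.1, 0.9, (6, 6))
        arr = (arr + arr.T) / 2
        np.fill_diagonal(arr, 1.0)
        rho = pd.DataFrame(arr, index=ids, columns=ids)
        q = pd.DataFrame(np.full((6, 6), 0.5), index=ids, columns=ids)
        net = st.build_network(rho, q, r_threshold=0.0, fdr=1.0)
        assert net.n_edges == 6 * 5 // 2


class TestGraphStats:
    def test_path_graph_closed_forms(self):
        net = _net_from_edges([("a", "b"), ("b", "c")])
        stats = st.graph_stats(net)
        assert stats.abc_index == pytest.approx(2 * math.sqrt(0.5))
        assert stats.ga_index == pytest.approx(2 * (2 * math.sqrt(2) / 3))

    def test_complete_graph_k4_ga(self):
        edges = list(itertools.combinations("abcd", 2))
        stats = st.graph_stats(_net_from_edges(edges))
        assert stats.ga_index == pytest.approx(6.0)

    def test_betweenness_matches_brute_force(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("b", "e"), ("e", "f")]
        net = _net_from_edges(edges)
        stats = st.graph_stats(net)
        g = net.graph
        nodes = list(g.nodes)
        # exhaustive shortest-path counting
        expect = dict.fromkeys(nodes, 0.0)
        for s, t in itertools.combinations(nodes, 2):
            paths = list(nx.all_shortest_paths(g, s, t))
            for v in nodes:
                if v in (s, t):
                    continue
                frac = sum(v in p for p in paths) / len(paths)
                expect[v] += frac
        n = len(nodes)
        scale = 2 / ((n - 1) * (n - 2))
        for v in nodes:
            assert stats.node_table.loc[v, "betweenness"] == pytest.approx(expect[v] * scale)

    def test_hub_count_and_tie_break(self):
        edges = [(f"hub", f"o{i}") for i in range(12)]
        stats = st.graph_stats(_net_from_edges(edges))
        assert len(stats.hubs) == 10
        assert stats.hubs[0] == "hub"
        # ties at degree 1 resolved lexicographically
        assert stats.hubs[1:] == sorted(stats.hubs[1:])

    def test_abc_ga_additive_over_components(self):
        net_a = _net_from_edges([("a", "b"), ("b", "c")])
        net_b = _net_from_edges([("x", "y")])
        combined = _net_from_edges([("a", "b"), ("b", "c"), ("x", "y")])
        for index in (st.abc_index, st.ga_index):
            assert index(combined.graph) == pytest.approx(
                index(net_a.graph) + index(net_b.graph))

    def test_bertz_formula(self):
        net = _net_from_edges([("a", "b"), ("b", "c")])
        m = 2
        expected = 2 * m * math.log2(2 * m) - (2 * math.log2(2))  # only deg-2 node contributes
        assert st.bertz_index(net.graph) == pytest.approx(expected)


class TestMetaNetwork:
    def test_disjoint_networks_sum_edges(self):
        a = _net_from_edges([("a", "b")], context=("BS", 48))
        b = _net_from_edges([("c", "d")], context=("RS", 48))
        meta = st.merge_meta([a, b])
        assert meta.n_edges == 2

    def test_identical_networks_keep_single_edge_with_provenance(self):
        a = _net_from_edges([("a", "b")], context=("BS", 48))
        b = _net_from_edges([("a", "b")], context=("BS", 62))
        meta = st.merge_meta([a, b])
        assert meta.n_edges == 1
        assert len(meta.graph["a"]["b"]["contexts"]) == 2

    def test_101_contexts_provenance_recount(self):
        comps = ["BS", "RS", "R", "S1", "L1", "Se"]
        ages = [48, 62, 76, 90, 106, 120, 141]
        nets = []
        for i in range(101):
            g = nx.gnm_random_graph(25, 35, seed=i)
            nets.append(_net_from_edges([(f"o{u}", f"o{v}") for u, v in g.edges],
                                        context=(comps[i % 6], ages[i % 7])))
        meta = st.merge_meta(nets)
        counts = {}
        for net in nets:
            for e in net.edge_set():
                counts[e] = counts.get(e, 0) + 1
        assert meta.n_edges == len(counts)
        for u, v in meta.graph.edges:
            assert len(meta.graph[u][v]["contexts"]) == counts[frozenset((u, v))]
        assert meta.n_edges <= sum(n.n_edges for n in nets)

    def test_two_cliques_give_two_modules(self):
        edges = list(itertools.combinations(["a1", "a2", "a3", "a4"], 2))
        edges += list(itertools.combinations(["b1", "b2", "b3", "b4"], 2))
        edges.append(("a1", "b1"))
        net = _net_from_edges(edges, context=("BS", 48))
        meta = st.merge_meta([net])
        mods = st.detect_modules(meta, seed=0)
        assert len(set(mods.membership.values())) == 2
        assert mods.membership["a1"] == mods.membership["a4"]
        assert mods.membership["a1"] != mods.membership["b1"]
        assert mods.modularity >= 0.0

    def test_planted_partition_recovery(self):
        g = nx.planted_partition_graph(2, 30, 0.3, 0.01, seed=4)
        net = _net_from_edges([(f"n{u}", f"n{v}") for u, v in g.edges], context=("BS", 48))
        mods = st.detect_modules(st.merge_meta([net]), seed=1)
        truth = {f"n{i}": (0 if i < 30 else 1) for i in range(60)}
        correct = 0
        for mid in set(mods.membership.values()):
            members = [n for n, m in mods.membership.items() if m == mid]
            votes = {}
            for n in members:
                votes[truth[n]] = votes.get(truth[n], 0) + 1
            correct += max(votes.values())
        assert correct / len(mods.membership) >= 0.95

    def test_module_composition_fractions_sum_to_one(self):
        a = _net_from_edges([("a", "b"), ("b", "c")], context=("BS", 48))
        b = _net_from_edges([("a", "b"), ("x", "y")], context=("Se", 141))
        mods = st.detect_modules(st.merge_meta([a, b]), seed=0)
        for (mod, axis), grp in mods.composition.groupby(["module", "axis"]):
            assert grp["fraction"].sum() == pytest.approx(1.0)


class TestEdgeJaccard:
    def test_identity_disjoint_and_partial(self):
        a = _net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        b = _net_from_edges([("b", "c"), ("c", "d"), ("d", "e")])
        c = _net_from_edges([("x", "y")])
        mat, graph = st.edge_jaccard([a, b, c], display_threshold=0.02)
        assert mat.iloc[0, 0] == 1.0
        assert mat.iloc[0, 2] == 0.0
        assert mat.iloc[0, 1] == pytest.approx(2 / 4)

    def test_empty_network_defined_zero(self, caplog):
        a = _net_from_edges([("a", "b")])
        b = AssocNetwork(graph=nx.Graph(), context=("BS", 48))
        with caplog.at_level("WARNING"):
            mat, _ = st.edge_jaccard([a, b])
        assert mat.iloc[0, 1] == 0.0


class TestEnrichment:
    @staticmethod
    def _brute_tail(k, n_pop, successes, draws):
        denom = comb(n_pop, draws)
        total = 0
        for x in range(k, min(successes, draws) + 1):
            if n_pop - successes >= draws - x:
                total += comb(successes, x) * comb(n_pop - successes, draws - x)
        return total / denom

    def test_matches_brute_force_on_random_small_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_nodes = int(rng.integers(4, 9))
            n_edges = int(rng.integers(3, 13))
            g = nx.gnm_random_graph(n_nodes, min(n_edges, n_nodes * (n_nodes - 1) // 2),
                                    seed=int(rng.integers(10 ** 6)))
            if g.number_of_edges() == 0:
                continue
            gg = nx.Graph()
            labels = {}
            for u, v in g.edges:
                gg.add_edge(f"o{u}", f"o{v}", rho=0.5, q=0.01, sign="pos")
            for n in gg.nodes:
                gg.nodes[n]["class"] = rng.choice(["A", "B", "C"])
            net = AssocNetwork(graph=gg, context=("all", "all"))
            res = st.class_enrichment(net, level="class")
            for r in res.table.itertuples():
                expected = self._brute_tail(r.k, len(list(gg.edges)), r.successes, r.draws)
                assert r.p == pytest.approx(expected, abs=1e-12)

    def test_single_label_pair_is_uninformative(self):
        net = _net_from_edges([("a", "b"), ("b", "c")])
        for n in net.graph.nodes:
            net.graph.nodes[n]["class"] = "A"
        res = st.class_enrichment(net, level="class")
        assert len(res.table) == 1
        assert res.table["p"].iloc[0] == pytest.approx(1.0)

    def test_every_edge_joining_two_classes_is_minimal_p(self):
        edges = [(f"a{i}", f"b{i}") for i in range(6)]
        net = _net_from_edges(edges)
        for n in net.graph.nodes:
            net.graph.nodes[n]["class"] = "A" if n.startswith("a") else "B"
        res = st.class_enrichment(net, level="class")
        tab = res.table.set_index(["class_a", "class_b"])
        assert tab.loc[("A", "B"), "p"] <= tab["p"].min() + 1e-15

    def test_overrepresentation_flag_rule(self):
        edges = [(f"a{i}", f"b{i}") for i in range(8)] + [("c1", "c2")]
        net = _net_from_edges(edges)
        for n in net.graph.nodes:
            net.graph.nodes[n]["class"] = n[0].upper()
        res = st.class_enrichment(net, level="class")
        flagged = res.table[res.table["flag"] == "overrepresented"]
        assert ((flagged["q"] < 0.05) & (flagged["k"] > flagged["expected"])).all()


class TestBinomialCooccurrence:
    def test_all_positive_everywhere_is_uninformative(self):
        net = _net_from_edges([("a", "b"), ("b", "c"), ("c", "d")])
        for n in net.graph.nodes:
            net.graph.nodes[n]["class"] = "A"
        res = st.binomial_cooccurrence(net, level="class")
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_closed_form_binomial_tail(self):
        # 12 edges globally: 9 pos / 3 neg, one pair all-negative
        edges = [(f"a{i}", f"b{i}") for i in range(9)] + [(f"c{i}", f"d{i}") for i in range(3)]
        signs = ["pos"] * 9 + ["neg"] * 3
        net = _net_from_edges(edges, signs=signs)
        for n in net.graph.nodes:
            net.graph.nodes[n]["class"] = "AB" if n[0] in "ab" else "CD"
        res = st.binomial_cooccurrence(net, level="class").set_index(["class_a", "class_b"])
        pi0 = 9 / 12
        from scipy.stats import binom

        # pair CD: 0 positives of 3
        lower = binom.cdf(0, 3, pi0)
        upper = binom.sf(-1, 3, pi0)
        expected = min(1.0, 2 * min(lower, upper))
        assert res.loc[("CD", "CD"), "p"] == pytest.approx(expected, abs=1e-12)


def test_write_graphml_roundtrip(tmp_path):
    net = _net_from_edges([("a", "b"), ("b", "c")], context=("BS", 48))
    meta = st.merge_meta([net])
    path = tmp_path / "meta.graphml"
    st.networks.write_graphml(meta, path)
    back = nx.read_graphml(path)
    assert back.number_of_edges() == 2
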