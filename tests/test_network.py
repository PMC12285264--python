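"""SparCC inference, network construction, topology and Zi-Pi classification."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from meadownet import (
    CorrelationResult,
    Network,
    build_network,
    classify_role,
    detect_modules,
    ego_network,
    extract_interdomain,
    prevalence_filter,
    sparcc,
    sparcc_pvalues,
    topology,
    zi_pi,
)
from meadownet.network import _variation_matrix

from conftest import make_table


def toy_network(edges, domains=None, abundances=None, provenance="whole"):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, sign="+" if w > 0 else "-")
    for node in g.nodes:
        g.nodes[node]["domain"] = (domains or {}).get(node, "fungi")
        g.nodes[node]["abundance"] = (abundances or {}).get(node, 0.1)
    return Network(g, provenance=provenance)


class TestPrevalenceFilter:
    def test_exactly_half_removed_strictly_more_retained(self):
        n = 36
        values = np.zeros((n, 3), dtype=int)
        values[:18, 0] = 5   # 18/36 = exactly 50% -> removed
        values[:19, 1] = 5   # 19/36 -> retained
        values[:, 2] = 1     # everywhere -> retained
        table = make_table(values)
        out = prevalence_filter(table, 0.5)
        assert out.taxon_ids == ["t2", "t3"]

    def test_all_present_unchanged(self, random_count_table):
        dense = make_table(random_count_table.values.astype(int) + 1)
        out = prevalence_filter(dense, 0.5)
        assert out.taxon_ids == dense.taxon_ids

    def test_empty_result_raises_with_advice(self):
        table = make_table(np.zeros((4, 2), dtype=int) + np.eye(4, 2, dtype=int))
        with pytest.raises(ValueError, match="threshold"):
            prevalence_filter(table, 0.9)


class TestSparcc:
    def test_three_taxon_exact_oracle(self):
        """D = 3 makes the basis-variance system exactly determined; solve it
        in closed form and compare."""
        rng = np.random.default_rng(1)
        x = rng.integers(1, 500, size=(40, 3))
        table = make_table(x)
        res = sparcc(table, n_resamples=0, n_exclusion_iterations=0)

        f = (x + 1) / (x + 1).sum(axis=1, keepdims=True)
        t = _variation_matrix(f)
        a, b, c = t[0, 1] + t[0, 2], t[0, 1] + t[1, 2], t[0, 2] + t[1, 2]
        s = (a + b + c) / 4
        w = np.array([a - s, b - s, c - s])
        for (i, j) in ((0, 1), (0, 2), (1, 2)):
            expected = (w[i] + w[j] - t[i, j]) / (2 * np.sqrt(w[i] * w[j]))
            assert res.r[i, j] == pytest.approx(np.clip(expected, -1, 1), abs=1e-8)

    def test_proportional_pair_detected_among_independents(self):
        rng = np.random.default_rng(2)
        n, d = 100, 22
        latent = np.exp(rng.normal(0, 1, size=(n, d)))
        latent[:, 1] = latent[:, 0] * 2.0  # perfectly proportional pair
        frac = latent / latent.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(5000, f) for f in frac])
        res = sparcc(make_table(counts), seed=0)
        assert res.r[0, 1] >= 0.9
        others = np.abs(res.r[2:, 2:][np.triu_indices(d - 2, 1)])
        assert np.median(others) < 0.3

    def test_deterministic_under_seed(self, random_count_table):
        dense = make_table(random_count_table.values.astype(int) + 1)
        r1 = sparcc(dense, seed=5).r
        r2 = sparcc(dense, seed=5).r
        np.testing.assert_array_equal(r1, r2)

    def test_symmetric_unit_diagonal_bounded(self, random_count_table):
        dense = make_table(random_count_table.values.astype(int) + 1)
        r = sparcc(dense, seed=0).r
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1).all()

    def test_all_zero_taxon_rejected(self):
        values = np.ones((6, 4), dtype=int)
        values[:, 2] = 0
        with pytest.raises(ValueError, match="prevalence"):
            sparcc(make_table(values))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError, match="3 taxa"):
            sparcc(make_table(np.ones((6, 2), dtype=int)))


class TestSparccPvalues:
    def test_p_respects_minimum_and_diagonal(self):
        rng = np.random.default_rng(3)
        table = make_table(rng.integers(1, 100, size=(20, 6)))
        res = sparcc(table, n_resamples=5, seed=0)
        p = sparcc_pvalues(table, res, n_permutations=19, seed=0, n_resamples=0)
        assert (p >= 1 / 20 - 1e-12).all()
        assert (np.diag(p) == 1).all()

    def test_planted_pair_gets_minimum_p(self):
        rng = np.random.default_rng(4)
        n, d = 60, 10
        latent = np.exp(rng.normal(0, 1, size=(n, d)))
        latent[:, 1] = latent[:, 0] * np.exp(rng.normal(0, 0.2, n))
        frac = latent / latent.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(3000, f) for f in frac])
        table = make_table(counts)
        res = sparcc(table, n_resamples=5, seed=0)
        p = sparcc_pvalues(table, res, n_permutations=99, seed=0, n_resamples=0)
        assert p[0, 1] == pytest.approx(1 / 100)

    def test_too_few_permutations_rejected(self):
        table = make_table(np.ones((6, 4), dtype=int))
        res = sparcc(table, n_resamples=0)
        with pytest.raises(ValueError, match="19"):
            sparcc_pvalues(table, res, n_permutations=10)


class TestBuildNetwork:
    def _corr(self, r01, p01):
        r = np.eye(3)
        r[0, 1] = r[1, 0] = r01
        p = np.ones((3, 3))
        p[0, 1] = p[1, 0] = p01
        return CorrelationResult(["a", "b", "c"], r, p)

    def test_weak_correlation_no_edge(self):
        net = build_network(self._corr(0.15, 0.001), {"a": "fungi", "b": "bacteria", "c": "fungi"}, dict.fromkeys("abc", 0.1))
        assert net.n_edges == 0

    def test_insignificant_correlation_no_edge(self):
        net = build_network(self._corr(0.5, 0.2), {"a": "fungi", "b": "bacteria", "c": "fungi"}, dict.fromkeys("abc", 0.1))
        assert net.n_edges == 0

    def test_passing_edge_built_with_sign_and_isolated_nodes_dropped(self):
        net = build_network(self._corr(-0.5, 0.01), {"a": "fungi", "b": "bacteria", "c": "fungi"}, dict.fromkeys("abc", 0.1))
        assert net.n_edges == 1 and net.n_nodes == 2
        assert net.graph.edges["a", "b"]["sign"] == "-"
        assert "c" not in net.graph

    def test_zero_correlations_give_empty_network(self):
        r = np.eye(2)
        corr = CorrelationResult(["a", "b"], r, np.ones((2, 2)))
        net = build_network(corr, {"a": "fungi", "b": "fungi"}, {"a": 0.5, "b": 0.5})
        assert net.n_nodes == 0 and net.n_edges == 0


class TestInterdomainAndEgo:
    def test_only_cross_domain_edges_survive(self):
        net = toy_network(
            [("f1", "f2", 0.5), ("f1", "b1", -0.4), ("b1", "b2", 0.3)],
            domains={"f1": "fungi", "f2": "fungi", "b1": "bacteria", "b2": "bacteria"},
        )
        inter = extract_interdomain(net)
        assert set(inter.graph.edges) == {("f1", "b1")}
        assert inter.n_nodes == 2
        assert inter.provenance == "interdomain"

    def test_fungus_only_network_becomes_empty(self):
        net = toy_network([("f1", "f2", 0.5)])
        inter = extract_interdomain(net)
        assert inter.n_nodes == 0

    def test_archaea_count_as_prokaryotes(self):
        net = toy_network(
            [("f1", "a1", 0.5)], domains={"f1": "fungi", "a1": "archaea"}
        )
        assert extract_interdomain(net).n_edges == 1

    def test_ego_star_signed_counts(self):
        edges = [("f", f"b{i}", 0.5) for i in range(3)] + [
            ("f", f"b{i}", -0.5) for i in range(3, 5)
        ] + [("b0", "b1", 0.9)]
        domains = {"f": "fungi"} | {f"b{i}": "bacteria" for i in range(5)}
        net = toy_network(edges, domains=domains)
        ego, (pos, neg) = ego_network(net, "f")
        assert (pos, neg) == (3, 2)
        assert ("b0", "b1") not in ego.graph.edges  # only focus-incident edges

    def test_isolated_focus_gives_single_node(self):
        net = toy_network([("b1", "b2", 0.5)], domains={"b1": "bacteria", "b2": "bacteria"})
        net.graph.add_node("f", domain="fungi", abundance=0.1)
        ego, counts = ego_network(net, "f")
        assert ego.n_nodes == 1 and counts == (0, 0)

    def test_missing_focus_rejected(self):
        net = toy_network([("a", "b", 0.5)])
        with pytest.raises(KeyError, match="focus"):
            ego_network(net, "zz")


class TestTopology:
    @pytest.mark.parametrize(
        "nodes,edges,expected",
        [
            (163, 2970, 36.442),   # whole leaf
            (536, 2470, 9.216),    # interdomain sediment
            (3, 3, 2.0),           # triangle
        ],
    )
    def test_average_degree_arithmetic(self, nodes, edges, expected):
        g = nx.gnm_random_graph(nodes, edges, seed=1)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = 0.5
        for n in g.nodes:
            g.nodes[n]["domain"] = "bacteria"
            g.nodes[n]["abundance"] = 0.01
        topo = topology(Network(g), seed=0)
        assert round(topo.average_degree, 3) == expected
        assert topo.positive_edges + topo.negative_edges == topo.total_edges

    def test_empty_network_flagged(self):
        topo = topology(Network(nx.Graph()))
        assert topo.total_nodes == 0 and not topo.modularity_defined


class TestModulesAndZiPi:
    def test_two_cliques_separated_with_high_q(self):
        g = nx.Graph()
        for base in (0, 5):
            for i in range(5):
                for j in range(i + 1, 5):
                    g.add_edge(base + i, base + j, weight=0.5, sign="+")
        g.add_edge(0, 5, weight=0.5, sign="+")
        for n in g.nodes:
            g.nodes[n]["domain"] = "fungi"
            g.nodes[n]["abundance"] = 0.1
        part = detect_modules(Network(g), seed=0)
        assert part.modularity > 0.4
        left = {part.assignment[i] for i in range(5)}
        right = {part.assignment[i] for i in range(5, 10)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_single_community_q_zero(self):
        g = nx.complete_graph(4)
        for u, v in g.edges:
            g.edges[u, v].update(weight=0.5, sign="+")
        for n in g.nodes:
            g.nodes[n].update(domain="fungi", abundance=0.1)
        net = Network(g)
        from meadownet import ModulePartition

        part = ModulePartition({n: 0 for n in g.nodes}, 0.0)
        q = nx.community.modularity(g, [set(g.nodes)])
        assert q == pytest.approx(0.0)
        roles = zi_pi(net, part)
        assert all(r.pi == 0.0 for r in roles)

    def test_q_matches_independent_recomputation(self):
        g = nx.gnm_random_graph(30, 60, seed=3)
        for u, v in g.edges:
            g.edges[u, v].update(weight=0.5, sign="+")
        for n in g.nodes:
            g.nodes[n].update(domain="fungi", abundance=0.1)
        part = detect_modules(Network(g), seed=0)
        comms: dict[int, set] = {}
        for node, m in part.assignment.items():
            comms.setdefault(m, set()).add(node)
        q = nx.community.modularity(g, list(comms.values()))
        assert part.modularity == pytest.approx(q, abs=1e-12)

    def test_pi_closed_forms(self):
        # node with 2 links in each of 2 modules: Pi = 1 - (0.5^2 + 0.5^2) = 0.5
        g = nx.star_graph(4)
        for u, v in g.edges:
            g.edges[u, v].update(weight=0.5, sign="+")
        for n in g.nodes:
            g.nodes[n].update(domain="fungi", abundance=0.1)
        net = Network(g)
        from meadownet import ModulePartition

        part = ModulePartition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1}, 0.0)
        roles = {r.node: r for r in zi_pi(net, part)}
        assert roles[0].pi == pytest.approx(0.5)
        assert roles[1].pi == 0.0  # all links inside its own module

    @pytest.mark.parametrize(
        "zi,pi,category",
        [
            (3.0, 0.7, "Network hub"),
            (3.0, 0.3, "Module hub"),
            (1.0, 0.7, "Connector"),
            (1.0, 0.3, "Peripheral"),
            (2.5, 0.62, "Peripheral"),  # thresholds are strict
        ],
    )
    def test_four_quadrant_classification(self, zi, pi, category):
        assert classify_role(zi, pi) == category

    def test_isolated_node_rejected(self):
        net = toy_network([("a", "b", 0.5)])
        net.graph.add_node("c", domain="fungi", abundance=0.1)
        from meadownet import ModulePartition

        part = ModulePartition({"a": 0, "b": 0, "c": 1}, 0.0)
        with pytest.raises(ValueError, match="[Ii]solated"):
            zi_pi(net, part)

    def test_categories_partition_all_nodes(self):
        g = nx.gnm_random_graph(40, 120, seed=4)
        for u, v in g.edges:
            g.edges[u, v].update(weight=0.5, sign="+")
        for n in g.nodes:
            g.nodes[n].update(domain="fungi", abundance=0.1)
        net = Network(g)
        part = detect_modules(net, seed=0)
        roles = zi_pi(net, part)
        assert len(roles) == 40
        assert {r.category for r in roles} <= {
            "Peripheral", "Connector", "Module hub", "Network hub"
        }
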