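import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pollenet.io_model import RelAbundanceTable
from pollenet.networks import (
    CoNetwork,
    bh_fdr,
    build_network,
    detect_modules,
    filter_genera,
    spearman_matrix,
    topology,
)


def _rel(arr, domain="bacteria"):
    arr = np.asarray(arr, dtype=float)
    idx = [f"t{i}" for i in range(arr.shape[0])]
    cols = [f"s{i}" for i in range(arr.shape[1])]
    return RelAbundanceTable(
        values=pd.DataFrame(arr, index=idx, columns=cols),
        taxonomy=pd.Series("u", index=idx),
        domain=domain,
    )


class TestFilterGenera:
    def _rel_with(self, occurrence, mean_ra, n_samples=10):
        """One genus with given occurrence and mean RA plus a filler genus."""
        row = np.zeros(n_samples)
        row[:occurrence] = mean_ra * n_samples / occurrence
        filler = (1.0 - row) / 1.0
        values = pd.DataFrame([row, filler], index=["target", "filler"],
                              columns=[f"s{i}" for i in range(n_samples)])
        return RelAbundanceTable(values=values,
                                 taxonomy=pd.Series("u", index=["target", "filler"]),
                                 domain="bacteria")

    def test_bacterial_occurrence_gate(self):
        rel = self._rel_with(occurrence=4, mean_ra=0.01)
        assert "target" not in filter_genera(rel, rel.sample_ids, "bacteria")

    def test_bacterial_abundance_gate(self):
        rel = self._rel_with(occurrence=6, mean_ra=4e-4)
        assert "target" not in filter_genera(rel, rel.sample_ids, "bacteria")
        rel = self._rel_with(occurrence=6, mean_ra=6e-4)
        assert "target" in filter_genera(rel, rel.sample_ids, "bacteria")

    def test_fungal_rule_ignores_occurrence(self):
        rel = self._rel_with(occurrence=1, mean_ra=2e-5)
        rel.domain = "fungi"
        assert "target" in filter_genera(rel, rel.sample_ids, "fungi")

    def test_empty_group_is_error(self):
        rel = self._rel_with(occurrence=5, mean_ra=0.01)
        with pytest.raises(ValueError, match="empty"):
            filter_genera(rel, [], "bacteria")


class TestSpearmanMatrix:
    def test_monotone_and_reversed_and_hand_value(self):
        values = pd.DataFrame(
            [[1, 2, 3, 4, 5], [5, 4, 3, 2, 1], [1, 2, 3, 4, 5]],
            index=list("abc"), columns=[f"s{i}" for i in range(5)], dtype=float,
        )
        rho, _ = spearman_matrix(values)
        assert rho.loc["a", "c"] == pytest.approx(1.0)
        assert rho.loc["a", "b"] == pytest.approx(-1.0)
        values4 = pd.DataFrame([[1, 2, 3, 4], [2, 1, 4, 3]], index=list("xy"),
                               columns=[f"s{i}" for i in range(4)], dtype=float)
        rho4, _ = spearman_matrix(values4)
        assert rho4.loc["x", "y"] == pytest.approx(0.6)

    def test_constant_profile_recorded_missing(self):
        values = pd.DataFrame([[1, 2, 3, 4], [2, 2, 2, 2], [4, 3, 2, 1]],
                              index=list("abc"),
                              columns=[f"s{i}" for i in range(4)], dtype=float)
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_matrix(values)
        assert np.isnan(rho.loc["a", "b"])
        assert np.isnan(p.loc["b", "c"])
        assert rho.loc["a", "c"] == pytest.approx(-1.0)

    def test_symmetry_and_unit_diagonal(self, rng):
        values = pd.DataFrame(rng.random((5, 8)), index=[f"t{i}" for i in range(5)])
        rho, _ = spearman_matrix(values)
        assert np.allclose(rho, rho.T)
        assert np.allclose(np.diag(rho), 1.0)


class TestBhFdr:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_equal_and_single(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        np.testing.assert_allclose(bh_fdr([0.7]), [0.7])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_order_preserving_and_capped(self, rng):
        p = rng.random(50)
        q = bh_fdr(p)
        assert (q <= 1).all()
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _matrices(rho_pairs, taxa):
    n = len(taxa)
    rho = pd.DataFrame(np.eye(n), index=taxa, columns=taxa)
    p = pd.DataFrame(np.ones((n, n)), index=taxa, columns=taxa)
    for a, b, r, pv in rho_pairs:
        rho.loc[a, b] = rho.loc[b, a] = r
        p.loc[a, b] = p.loc[b, a] = pv
    return rho, p


class TestBuildNetwork:
    def test_rho_below_gate_never_an_edge(self):
        taxa = ["b1", "b2"]
        rho, p = _matrices([("b1", "b2", 0.64, 1e-6)], taxa)
        net = build_network(rho, p, "bacteria", "Self_open",
                           {t: "bacteria" for t in taxa})
        assert net.n_edges == 0

    def test_exact_threshold_is_retained(self):
        taxa = ["b1", "b2"]
        rho, p = _matrices([("b1", "b2", 0.65, 1e-6)], taxa)
        net = build_network(rho, p, "bacteria", "Self_open",
                           {t: "bacteria" for t in taxa})
        assert net.n_edges == 1

    def test_cross_domain_rejects_within_domain_pairs(self):
        taxa = ["b1", "b2", "f1"]
        domains = {"b1": "bacteria", "b2": "bacteria", "f1": "fungi"}
        rho, p = _matrices([("b1", "b2", 0.9, 1e-9), ("b1", "f1", 0.9, 1e-9)], taxa)
        net = build_network(rho, p, "cross_domain", "Cross_open", domains)
        assert set(map(frozenset, net.graph.edges)) == {frozenset(("b1", "f1"))}
        assert all(net.graph.nodes[a]["domain"] != net.graph.nodes[b]["domain"]
                   for a, b in net.graph.edges)

    def test_isolated_nodes_dropped_and_fdr_monotone(self, rng):
        taxa = [f"b{i}" for i in range(8)]
        pairs = []
        for i, j in itertools.combinations(range(8), 2):
            pairs.append((f"b{i}", f"b{j}", float(rng.uniform(-1, 1)),
                          float(rng.uniform(0, 0.2))))
        rho, p = _matrices(pairs, taxa)
        domains = {t: "bacteria" for t in taxa}
        gated = build_network(rho, p, "bacteria", "g", domains)
        ungated = build_network(rho, p, "bacteria", "g", domains, q_max=1.1)
        gated_edges = set(map(frozenset, gated.graph.edges))
        ungated_edges = set(map(frozenset, ungated.graph.edges))
        assert gated_edges <= ungated_edges  # dropping the FDR gate only adds
        assert all(d > 0 for _, d in gated.graph.degree)

    def test_edges_invariant_to_sample_reordering(self, rng):
        arr = rng.dirichlet(np.ones(10), size=8).T
        rel = _rel(arr)
        cols = list(rel.values.columns)
        rho1, p1 = spearman_matrix(rel.values[cols])
        shuffled = list(rng.permutation(cols))
        rho2, p2 = spearman_matrix(rel.values[shuffled])
        domains = {t: "bacteria" for t in rel.values.index}
        n1 = build_network(rho1, p1, "bacteria", "g", domains, rho_min=0.3, q_max=0.9)
        n2 = build_network(rho2, p2, "bacteria", "g", domains, rho_min=0.3, q_max=0.9)
        assert set(map(frozenset, n1.graph.edges)) == set(map(frozenset, n2.graph.edges))


def _net(edges):
    g = nx.Graph()
    for a, b in edges:
        g.add_edge(a, b, rho=0.9, q=0.01, sign="positive")
    return CoNetwork(graph=g, group="toy", mode="bacteria")


def _brute_modularity(g, partition):
    m = g.number_of_edges()
    q = 0.0
    for comm in partition:
        e_c = sum(1 for a, b in g.edges if a in comm and b in comm)
        d_c = sum(d for n, d in g.degree if n in comm)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


class TestModules:
    def test_two_disjoint_triangles(self):
        net = _net([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        modules, q = detect_modules(net, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(modules.values())) == 2

    def test_complete_graph_single_community(self):
        net = _net(itertools.combinations(range(5), 2))
        _, q = detect_modules(net, seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        edges = [(int(a), int(b)) for a, b in
                 rng.integers(0, 15, size=(40, 2)) if a != b]
        m1, q1 = detect_modules(_net(edges), seed=42)
        m2, q2 = detect_modules(_net(edges), seed=42)
        assert m1 == m2 and q1 == q2

    def test_edgeless_flagged(self):
        net = CoNetwork(graph=nx.Graph(), group="toy", mode="fungi")
        with pytest.warns(UserWarning, match="edgeless"):
            modules, q = detect_modules(net)
        assert modules == {} and q is None

    def test_reported_q_matches_brute_force_and_near_optimum(self, rng):
        """On graphs small enough to enumerate every partition, the Louvain
        Q must equal the closed-form Q of its own partition and come within
        0.02 of the global optimum."""
        from itertools import combinations

        def partitions(nodes):
            if not nodes:
                yield []
                return
            first, rest = nodes[0], nodes[1:]
            for part in partitions(rest):
                for i in range(len(part)):
                    yield part[:i] + [[first] + part[i]] + part[i + 1:]
                yield [[first]] + part

        for trial in range(5):
            g = nx.gnp_random_graph(7, 0.45, seed=trial)
            if g.number_of_edges() < 2:
                continue
            net = CoNetwork(graph=g, group="toy", mode="bacteria")
            modules, q = detect_modules(net, seed=1)
            by_mod = {}
            for node, mod in modules.items():
                by_mod.setdefault(mod, set()).add(node)
            assert q == pytest.approx(_brute_modularity(g, by_mod.values()))
            best = max(_brute_modularity(g, [set(c) for c in part])
                       for part in partitions(list(g.nodes)))
            assert q >= best - 0.02

    def test_planted_three_block_partition_recovered(self):
        """Three planted cliques joined by single bridges are recovered
        with near-perfect node-module agreement."""
        g = nx.Graph()
        blocks = [list(range(i * 5, (i + 1) * 5)) for i in range(3)]
        for blk in blocks:
            g.add_edges_from(itertools.combinations(blk, 2))
        g.add_edge(0, 5)
        g.add_edge(5, 10)
        net = CoNetwork(graph=g, group="toy", mode="bacteria")
        modules, _ = detect_modules(net, seed=0)
        from sklearn.metrics import adjusted_rand_score

        truth = [i // 5 for i in range(15)]
        found = [modules[i] for i in range(15)]
        assert adjusted_rand_score(truth, found) >= 0.9


class TestTopology:
    def test_complete_graph_identities(self):
        net = _net(itertools.combinations(range(4), 2))
        t = topology(net)
        assert t.density == pytest.approx(1.0)
        assert t.clustering_coefficient == pytest.approx(1.0)
        assert t.diameter == 1.0
        assert t.avg_path_length == 1.0
        assert t.pct_positive_edges == 100.0

    def test_path_graph_enumeration(self):
        net = _net([("A", "B"), ("B", "C")])
        t = topology(net)
        assert t.avg_degree == pytest.approx(4 / 3)
        assert t.diameter == 2.0
        assert t.avg_path_length == pytest.approx(4 / 3)

    def test_disconnected_uses_within_component_pairs(self):
        net = _net([("A", "B"), ("C", "D"), ("D", "E")])
        t = topology(net)
        assert t.diameter == 2.0
        assert t.avg_path_length == pytest.approx((1 + 1 + 1 + 2) / 4)

    def test_negative_edges_counted(self):
        g = nx.Graph()
        g.add_edge("a", "b", rho=0.9, q=0.01, sign="positive")
        g.add_edge("b", "c", rho=-0.8, q=0.01, sign="negative")
        t = topology(CoNetwork(graph=g, group="g", mode="bacteria"))
        assert t.pct_positive_edges == pytest.approx(50.0)
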