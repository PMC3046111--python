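"""Cohesiveness clustering, module selection, gene-set enrichment."""

import itertools

import networkx as nx
import numpy as np
import pytest

from keymir.errors import InputError, NotFoundError, ParameterError
from keymir.modules import (FunctionalModule, GeneSet, GeneSetCollection,
                            cluster_one, cohesiveness, density, enrich,
                            grow_cluster, largest_module, overlap_score)


def weighted_graph(edges, weight=1.0):
    net = nx.Graph()
    for e in edges:
        if len(e) == 3:
            a, b, w = e
        else:
            (a, b), w = e, weight
        net.add_edge(a, b, confidence=w)
    return net


def clique(names, weight=1.0):
    return [(a, b, weight) for a, b in itertools.combinations(names, 2)]


def brute_force_cohesiveness(net, members, penalty):
    w_in = sum(net.edges[a, b]["confidence"]
               for a, b in itertools.combinations(sorted(members), 2)
               if net.has_edge(a, b))
    w_bound = sum(net.edges[a, b]["confidence"] for a, b in net.edges
                  if (a in members) != (b in members))
    return w_in / (w_in + w_bound + penalty * len(members))


class TestCohesiveness:
    def test_closed_triangle_penalty_zero(self):
        net = weighted_graph(clique("ABC"))
        assert cohesiveness(net, "ABC", penalty=0.0) == pytest.approx(1.0)

    def test_closed_triangle_default_penalty(self):
        net = weighted_graph(clique("ABC"))
        assert cohesiveness(net, "ABC", penalty=2.0) == pytest.approx(1 / 3)

    def test_single_node_with_external_edge(self):
        net = weighted_graph([("A", "B", 1.0)])
        assert cohesiveness(net, {"A"}, penalty=0.0) == pytest.approx(0.0)

    def test_empty_member_set_rejected(self):
        net = weighted_graph(clique("ABC"))
        with pytest.raises(ParameterError):
            cohesiveness(net, set())

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for trial in range(20):
            g = nx.gnp_random_graph(int(rng.integers(8, 50)), 0.25,
                                    seed=int(rng.integers(2**31)))
            net = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
            for a, b in net.edges:
                net.edges[a, b]["confidence"] = float(rng.uniform(0.5, 1.0))
            nodes = sorted(net.nodes)
            members = set(rng.choice(nodes, size=min(6, len(nodes)),
                                     replace=False))
            expected = brute_force_cohesiveness(net, members, 2.0)
            assert cohesiveness(net, members) == pytest.approx(expected,
                                                               abs=1e-12)


class TestGrowCluster:
    def test_isolated_clique_fully_recovered(self):
        net = weighted_graph(clique("ABCD"))
        assert grow_cluster(net, "B") == {"A", "B", "C", "D"}

    def test_isolated_seed_stays_singleton(self):
        net = weighted_graph(clique("ABC"))
        net.add_node("X")
        assert grow_cluster(net, "X") == {"X"}

    def test_bridged_cliques_stay_separate(self):
        c1 = [f"a{i}" for i in range(5)]
        c2 = [f"b{i}" for i in range(5)]
        net = weighted_graph(clique(c1) + clique(c2) +
                             [("a0", "b0", 1.0)])
        assert grow_cluster(net, "a3") == set(c1)

    def test_growth_never_decreases_cohesiveness(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(25, 0.2, seed=8)
        net = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for a, b in net.edges:
            net.edges[a, b]["confidence"] = float(rng.uniform(0.7, 1.0))
        for seed_node in sorted(net.nodes)[:8]:
            grown = grow_cluster(net, seed_node)
            assert cohesiveness(net, grown) >= \
                cohesiveness(net, {seed_node}) - 1e-12


class TestClusterOne:
    def test_two_disjoint_cliques_found(self):
        c1 = [f"a{i}" for i in range(5)]
        c2 = [f"b{i}" for i in range(5)]
        net = weighted_graph(clique(c1) + clique(c2))
        net.add_nodes_from(["x1", "x2", "x3"])
        modules = cluster_one(net)
        assert len(modules) == 2
        assert {frozenset(c1), frozenset(c2)} == {m.members for m in modules}

    def test_isolated_nodes_give_empty_list(self):
        net = nx.Graph()
        net.add_nodes_from("ABCDE")
        assert cluster_one(net) == []

    def test_overlap_merge_collapses_duplicates(self):
        assert overlap_score({"a", "b", "c"}, {"a", "b", "c"}) == 1.0
        assert overlap_score({"a", "b"}, {"c", "d"}) == 0.0
        assert overlap_score({"a", "b", "c", "d"},
                             {"a", "b", "c"}) == pytest.approx(9 / 12)

    def test_deterministic_under_node_order_shuffle(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(30, 0.2, seed=3)
        base = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
        for a, b in base.edges:
            base.edges[a, b]["confidence"] = float(rng.uniform(0.7, 1.0))
        reference = cluster_one(base)
        for _ in range(3):
            shuffled = nx.Graph()
            nodes = list(base.nodes)
            rng.shuffle(nodes)
            shuffled.add_nodes_from(nodes)
            edges = list(base.edges(data=True))
            rng.shuffle(edges)
            shuffled.add_edges_from(edges)
            result = cluster_one(shuffled)
            assert [m.members for m in result] == \
                [m.members for m in reference]

    def test_planted_modules_recovered_in_target_subnetworks(self, bundle):
        """Planted members are always inside the recovered module whenever
        a module is returned; recovery Jaccard is high on average (a hub
        genuinely cohesive with the module may legitimately join it)."""
        from keymir.modules import target_subnetwork
        keys = sorted(bundle.truth.planted_key_mirnas)
        jaccards = []
        for i, mirna in enumerate(keys):
            planted = bundle.truth.planted_modules[
                i % len(bundle.truth.planted_modules)]
            sub = target_subnetwork(bundle.network,
                                    bundle.target_map.genes(mirna))
            found = cluster_one(sub)
            if not found:
                jaccards.append(0.0)
                continue
            best = max(found,
                       key=lambda m: len(m.members & planted)
                       / len(m.members | planted))
            assert planted <= best.members
            jaccards.append(len(best.members & planted)
                            / len(best.members | planted))
        assert np.mean(jaccards) >= 0.85


class TestLargestModule:
    def module(self, members, coh):
        return FunctionalModule(frozenset(members), coh, 1.0)

    def test_largest_by_size(self):
        big = self.module("abcde", 0.2)
        small = self.module("xyz", 0.9)
        assert largest_module([small, big]) is big

    def test_tie_broken_by_cohesiveness(self):
        m1 = self.module("abcd", 0.5)
        m2 = self.module("wxyz", 0.7)
        assert largest_module([m1, m2]) is m2

    def test_singleton_list(self):
        m = self.module("abc", 0.4)
        assert largest_module([m]) is m

    def test_empty_list_raises(self):
        with pytest.raises(NotFoundError):
            largest_module([])


class TestEnrich:
    def collection(self, **sets):
        coll = GeneSetCollection()
        for set_id, members in sets.items():
            coll.add(GeneSet(set_id, "", frozenset(members)))
        return coll

    def test_gene_set_equal_to_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        module = FunctionalModule(frozenset(["g0", "g1", "g2"]), 0.5, 1.0)
        results = enrich(module, self.collection(ALL=universe), universe)
        assert results[0].overlap == 3
        assert results[0].p_value == pytest.approx(1.0)

    def test_exact_hypergeometric_worked_example(self):
        # |U|=10, |set|=5, |module|=3, overlap=3: p = C(5,3)/C(10,3) = 1/12
        universe = {f"g{i}" for i in range(10)}
        module = FunctionalModule(frozenset(["g0", "g1", "g2"]), 0.5, 1.0)
        results = enrich(module,
                         self.collection(S={"g0", "g1", "g2", "g3", "g4"}),
                         universe)
        assert results[0].p_value == pytest.approx(1 / 12, abs=1e-12)

    def test_zero_overlap_p_at_most_one(self):
        universe = {f"g{i}" for i in range(10)}
        module = FunctionalModule(frozenset(["g0", "g1", "g2"]), 0.5, 1.0)
        results = enrich(module, self.collection(S={"g8", "g9"}), universe)
        assert results[0].overlap == 0
        assert 0.0 < results[0].p_value <= 1.0

    def test_bh_adjustment_preserves_order(self, bundle):
        from keymir.modules import target_subnetwork
        mirna = sorted(bundle.truth.planted_key_mirnas)[0]
        sub = target_subnetwork(bundle.network,
                                bundle.target_map.genes(mirna))
        found = cluster_one(sub)
        module = largest_module(found)
        results = enrich(module, bundle.gene_sets, set(bundle.network.nodes))
        ps = [r.p_value for r in results]
        adj = [r.adjusted_p for r in results]
        assert ps == sorted(ps)
        assert adj == sorted(adj)
        assert all(a >= p for p, a in zip(ps, adj))

    def test_empty_universe_rejected(self):
        module = FunctionalModule(frozenset(["g0"]), 0.5, 1.0)
        with pytest.raises(ParameterError):
            enrich(module, self.collection(S={"g0"}), set())

    def test_module_outside_universe_rejected(self):
        module = FunctionalModule(frozenset(["g0", "zz"]), 0.5, 1.0)
        with pytest.raises(InputError):
            enrich(module, self.collection(S={"g0"}), {"g0", "g1"})

    def test_gmt_round_trip(self, tmp_path, bundle):
        path = tmp_path / "sets.gmt"
        bundle.gene_sets.write_gmt(path)
        back = GeneSetCollection.read_gmt(path)
        assert {s.set_id: s.members for s in back} == \
            {s.set_id: s.members for s in bundle.gene_sets}
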