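"""Mass-action equilibrium solver, perturbation responses, dynamic score."""

import math

import networkx as nx
import numpy as np
import pytest
from scipy import optimize

from keymir.errors import ParameterError, UndefinedResultError
from keymir.network import attach_abundance
from keymir.perturbation import (correlate, dynamic_score_from_sizes,
                                 equilibrate, perturb,
                                 perturbed_subgroup_size, score_all_mirnas)


def make_net(edges, totals):
    net = nx.Graph()
    net.add_nodes_from(totals)
    for a, b in edges:
        net.add_edge(a, b, confidence=1.0)
    attach_abundance(net, totals)
    return net


def oracle_equilibrium(edges, totals, K):
    """Independent high-precision root-finder for the same equations."""
    nodes = sorted(totals)
    index = {v: i for i, v in enumerate(nodes)}
    nbrs = {v: set() for v in nodes}
    for a, b in edges:
        nbrs[a].add(b)
        nbrs[b].add(a)

    def residual(free):
        return [free[index[v]] * (1 + K * sum(free[index[u]]
                                              for u in nbrs[v]))
                - totals[v] for v in nodes]

    free0 = np.array([totals[v] for v in nodes])
    sol = optimize.fsolve(residual, free0, xtol=1e-13)
    return dict(zip(nodes, sol))


class TestEquilibrate:
    def test_edgeless_network_free_equals_total(self):
        net = make_net([], {"A": 2.0, "B": 0.5, "C": 0.0})
        state = equilibrate(net)
        for node, total in (("A", 2.0), ("B", 0.5)):
            assert state.free[node] == pytest.approx(total, rel=1e-9)
        assert state.complex == {}

    def test_zero_association_constant_is_no_binding(self):
        net = make_net([("A", "B")], {"A": 1.0, "B": 3.0})
        state = equilibrate(net, K=0.0)
        assert state.free["A"] == pytest.approx(1.0, rel=1e-9)
        assert state.free["B"] == pytest.approx(3.0, rel=1e-9)

    def test_two_node_closed_form(self):
        # K(T - c)^2 = c with T=1, K=1: c = (3 - sqrt(5))/2
        net = make_net([("A", "B")], {"A": 1.0, "B": 1.0})
        state = equilibrate(net, tol=1e-12)
        golden = (3 - math.sqrt(5)) / 2
        assert state.free["A"] == pytest.approx(1 - golden, abs=1e-9)
        assert state.complex[("A", "B")] == pytest.approx(golden, abs=1e-9)

    def test_mass_conservation_on_synthetic_network(self, bundle):
        net = bundle.network
        state = equilibrate(net, tol=1e-10)
        assert state.residual < 1e-10
        for node in list(net.nodes)[:50]:
            bound = sum(v for (a, b), v in state.complex.items()
                        if node in (a, b))
            total = net.nodes[node]["abundance"]
            assert state.free[node] + bound == pytest.approx(total,
                                                             rel=1e-8)

    def test_invariant_to_damping(self):
        net = make_net([("A", "B"), ("B", "C")],
                       {"A": 2.0, "B": 1.0, "C": 0.3})
        s1 = equilibrate(net, damping=0.5, tol=1e-12)
        s2 = equilibrate(net, damping=0.3, tol=1e-12)
        for v in "ABC":
            assert s1.free[v] == pytest.approx(s2.free[v], abs=1e-10)

    def test_negative_abundance_rejected(self):
        net = make_net([("A", "B")], {"A": 1.0, "B": 1.0})
        net.nodes["B"]["abundance"] = -1.0
        with pytest.raises(Exception, match="negative abundance"):
            equilibrate(net)


class TestPerturb:
    def test_identity_fold_returns_baseline(self):
        net = make_net([("A", "B"), ("B", "C")],
                       {"A": 1.0, "B": 2.0, "C": 0.5})
        baseline = equilibrate(net, tol=1e-12)
        result = perturb(net, baseline, {"A"}, fold=1.0, tol=1e-12)
        for response in result.response.values():
            assert response == pytest.approx(1.0, abs=1e-8)
        assert result.dynamic_score == 0.0

    def test_isolated_source_does_not_propagate(self):
        net = make_net([("A", "B")], {"A": 1.0, "B": 1.0, "X": 5.0})
        baseline = equilibrate(net, tol=1e-12)
        result = perturb(net, baseline, {"X"}, fold=0.5, tol=1e-12)
        assert all(r == pytest.approx(1.0, abs=1e-9)
                   for r in result.response.values())

    def test_path_matches_root_finder_oracle(self):
        edges = [("A", "B"), ("B", "C")]
        totals = {"A": 1.0, "B": 1.0, "C": 1.0}
        net = make_net(edges, totals)
        baseline = equilibrate(net, tol=1e-12)
        result = perturb(net, baseline, {"A"}, fold=0.5, tol=1e-12)
        before = oracle_equilibrium(edges, totals, K=1.0)
        after = oracle_equilibrium(edges, {**totals, "A": 0.5}, K=1.0)
        for node in ("B", "C"):
            expected = max(after[node] / before[node],
                           before[node] / after[node])
            assert result.response[node] == pytest.approx(expected, abs=1e-8)

    def test_empty_source_set_rejected(self):
        net = make_net([("A", "B")], {"A": 1.0, "B": 1.0})
        baseline = equilibrate(net)
        with pytest.raises(ParameterError):
            perturb(net, baseline, set())

    def test_sources_excluded_from_counting(self):
        net = make_net([("A", "B")], {"A": 5.0, "B": 1.0})
        baseline = equilibrate(net, tol=1e-12)
        result = perturb(net, baseline, {"A"}, fold=0.5, tol=1e-12)
        assert set(result.response) == {"B"}


class TestScores:
    @pytest.mark.parametrize("threshold,expected", [(1.2, 2), (2.0, 1)])
    def test_subgroup_counting(self, threshold, expected):
        responses = {"a": 1.0, "b": 1.3, "c": 2.5}
        assert perturbed_subgroup_size(responses, threshold) == expected

    def test_all_unity_gives_empty_subgroup(self):
        assert perturbed_subgroup_size({"a": 1.0, "b": 1.0}, 1.01) == 0

    def test_threshold_below_one_rejected(self):
        with pytest.raises(ParameterError):
            perturbed_subgroup_size({"a": 1.5}, 0.9)

    @pytest.mark.parametrize("sizes,expected", [
        ({2.0: 4, 1.2: 5}, 0.8),
        ({2.0: 0, 1.2: 0}, 0.0),
        ({2.0: 3, 1.2: 3}, 1.0),
    ])
    def test_dynamic_score_ratio(self, sizes, expected):
        assert dynamic_score_from_sizes(sizes) == pytest.approx(expected)

    def test_random_perturbations_stay_in_unit_interval(self):
        rng = np.random.default_rng(3)
        g = nx.gnp_random_graph(20, 0.15, seed=5)
        net = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
        nx.set_edge_attributes(net, 1.0, "confidence")
        attach_abundance(net, {v: float(rng.lognormal(1.5, 1.2))
                               for v in net.nodes})
        baseline = equilibrate(net, tol=1e-10)
        nodes = sorted(net.nodes)
        for _ in range(50):
            sources = rng.choice(nodes, size=int(rng.integers(1, 6)),
                                 replace=False)
            fold = float(rng.choice([0.2, 0.5, 2.0, 5.0]))
            result = perturb(net, baseline, set(sources), fold=fold)
            assert 0.0 <= result.dynamic_score <= 1.0
            sizes = [result.subgroup_sizes[t]
                     for t in sorted(result.subgroup_sizes)]
            assert sizes == sorted(sizes, reverse=True)


class TestScoreAllMirnas:
    def test_isolated_targets_score_zero(self):
        from keymir.network import TargetMap, TargetRecord
        net = make_net([("A", "B")], {"A": 1.0, "B": 1.0, "X": 9.0,
                                      "Y": 4.0})
        tm = TargetMap({"miR-iso": [TargetRecord("X", "validated"),
                                    TargetRecord("Y", "validated")]})
        rec, = score_all_mirnas(net, tm)
        assert rec.dynamic_score == 0.0

    def test_identical_target_sets_identical_scores(self, bundle):
        from keymir.network import TargetMap
        mirna = sorted(bundle.truth.planted_key_mirnas)[0]
        entry = bundle.target_map.entries[mirna]
        tm = TargetMap({"copy1": entry, "copy2": entry})
        rec1, rec2 = score_all_mirnas(bundle.network, tm)
        assert rec1.dynamic_score == rec2.dynamic_score
        assert rec1.subgroup_sizes == rec2.subgroup_sizes

    def test_no_in_network_target_is_undefined(self):
        from keymir.network import TargetMap, TargetRecord
        net = make_net([("A", "B")], {"A": 1.0, "B": 1.0})
        tm = TargetMap({"m": [TargetRecord("Z", "validated")]})
        rec, = score_all_mirnas(net, tm)
        assert rec.dynamic_score is None

    def test_dominant_sources_outscore_scarce_sources(self):
        """A source whose free concentration dominates its partners'
        binding pushes them past both fold thresholds; a scarce source
        (negligible free concentration) perturbs nothing, so its dynamic
        score is 0 by the empty-subgroup convention."""
        from keymir.network import TargetMap, TargetRecord
        edges, totals = [], {}
        for tag, hub_total in (("D", 50.0), ("S", 1e-3)):
            totals[f"{tag}hub"] = hub_total
            for i in range(10):
                leaf = f"{tag}leaf{i}"
                edges.append((f"{tag}hub", leaf))
                totals[leaf] = 0.5
        net = make_net(edges, totals)
        tm = TargetMap({"dominant": [TargetRecord("Dhub", "validated")],
                        "scarce": [TargetRecord("Shub", "validated")]})
        recs = {r.mirna_id: r for r in score_all_mirnas(net, tm)}
        assert recs["dominant"].dynamic_score > recs["scarce"].dynamic_score
        assert recs["dominant"].dynamic_score > 0.9
        assert recs["scarce"].dynamic_score == 0.0


class TestCorrelate:
    def test_perfect_correlation(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0}
        r, p, n = correlate(x, x)
        assert r == pytest.approx(1.0)
        assert n == 3

    def test_perfect_anticorrelation(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0}
        y = {k: -v for k, v in x.items()}
        r, _, _ = correlate(x, y)
        assert r == pytest.approx(-1.0)

    def test_four_point_closed_form(self):
        x = dict(zip("abcd", [0.1, 0.4, 0.5, 0.9]))
        y = dict(zip("abcd", [2.0, 1.0, 3.0, 4.0]))
        r, p, n = correlate(x, y)
        assert r == pytest.approx(0.7423914319063353, abs=1e-12)
        assert 0.0 < p <= 1.0

    def test_undefined_pairs_dropped(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": None, "e": float("nan")}
        y = {"a": 1.0, "b": 2.1, "c": 2.9, "d": 4.0, "e": 5.0}
        _, _, n = correlate(x, y)
        assert n == 3

    def test_too_few_pairs_undefined(self):
        with pytest.raises(UndefinedResultError):
            correlate({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
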