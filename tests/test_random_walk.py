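import math

import numpy as np
import pytest

from metamda.mmd_graph import GraphError, HeteroGraph, NodeRegistry
from metamda.random_walk import (WalkConfig, generate_corpus, metabolite_step_probs,
                                 rho, sigmoid_gate, typed_step_probs)
from metamda.transition_model import EdgeTypeTransitionMatrix, init_uniform

from conftest import random_hetero_graph


class TestGate:
    def test_rho_is_one_without_metabolite_edges(self, toy_graph):
        # m3 has an ss edge but no sm edges: T = 0
        assert rho(toy_graph, "m3") == 1.0

    def test_rho_is_zero_without_same_type_neighbors(self, toy_graph):
        # d2 would have T=0 too; build the other boundary explicitly
        reg = NodeRegistry.build(["m1", "m2"], ["c1"], [])
        g = HeteroGraph(reg, {"sm": {("m1", "c1"): 1.0}})
        assert rho(g, "m1") == 0.0

    def test_sigmoid_midpoint_and_closed_form(self):
        assert sigmoid_gate(0.85) == pytest.approx(0.5)
        assert sigmoid_gate(0.95) == pytest.approx(1 / (1 + math.exp(-10)))

    def test_rho_uses_max_same_type_neighbor_similarity(self, toy_graph):
        # m1: metabolite edge exists, same-type weights 0.9 and 0.7
        assert rho(toy_graph, "m1") == pytest.approx(sigmoid_gate(0.9))

    def test_rho_rejects_metabolite_nodes(self, toy_graph):
        with pytest.raises(GraphError):
            rho(toy_graph, "c1")

    def test_gate_strictly_monotone(self):
        xs = np.linspace(0, 1, 100)
        ys = [sigmoid_gate(x) for x in xs]
        assert all(b > a for a, b in zip(ys, ys[1:]))


class TestMetaboliteStep:
    def test_uniform_transition_matrix_cancels(self, toy_graph):
        ids, p = metabolite_step_probs(toy_graph, init_uniform(), "m1", "c1")
        assert ids == ["m1", "m2", "c2", "d1"]
        np.testing.assert_allclose(p, 0.25)

    def test_edge_type_coupling_reweights(self, toy_graph):
        # from m1 (incoming sm), set M[sm, sm] = 2 vs 1 elsewhere:
        # neighbors m1, m2 get factor 2; c2, d1 get 1 -> (1/3, 1/3, 1/6, 1/6)
        vals = np.ones((5, 5))
        vals[1, 1] = 2.0  # sm is edge type index 1
        M = EdgeTypeTransitionMatrix(("ss", "sm", "mm", "dm", "dd"), vals)
        ids, p = metabolite_step_probs(toy_graph, M, "m1", "c1")
        np.testing.assert_allclose(p, [1 / 3, 1 / 3, 1 / 6, 1 / 6])

    def test_three_neighbor_factor_example(self):
        # single sm, mm, dm neighbor; factors (2,1,1) -> (0.5, 0.25, 0.25)
        reg = NodeRegistry.build(["m1"], ["c1", "c2"], ["d1"])
        g = HeteroGraph(reg, {"sm": {("m1", "c1"): 1.0},
                              "mm": {("c1", "c2"): 1.0},
                              "dm": {("d1", "c1"): 1.0}})
        vals = np.ones((5, 5))
        vals[1, 1] = 2.0
        M = EdgeTypeTransitionMatrix(("ss", "sm", "mm", "dm", "dd"), vals)
        ids, p = metabolite_step_probs(g, M, "m1", "c1")
        assert ids == ["m1", "c2", "d1"]
        np.testing.assert_allclose(p, [0.5, 0.25, 0.25])

    def test_walk_start_has_no_coupling_factor(self, toy_graph):
        vals = np.ones((5, 5)) * 3.0
        M = EdgeTypeTransitionMatrix(("ss", "sm", "mm", "dm", "dd"), vals)
        _, p = metabolite_step_probs(toy_graph, M, None, "c1")
        np.testing.assert_allclose(p, 0.25)

    def test_isolated_metabolite_truncates(self, toy_graph):
        ids, p = metabolite_step_probs(toy_graph, init_uniform(), None, "c3")
        assert ids == [] and p.size == 0

    def test_single_neighbor_gets_probability_one(self):
        reg = NodeRegistry.build(["m1"], ["c1"], [])
        g = HeteroGraph(reg, {"sm": {("m1", "c1"): 1.0}})
        ids, p = metabolite_step_probs(g, init_uniform(), None, "c1")
        assert ids == ["m1"]
        np.testing.assert_allclose(p, [1.0])


class TestTypedStep:
    def test_two_block_example(self):
        # rho = 0.5, same-type sims (0.9, 0.6), two metabolites
        reg = NodeRegistry.build(["v", "a", "b"], ["c1", "c2"], [])
        g = HeteroGraph(reg, {"ss": {("a", "v"): 0.9, ("b", "v"): 0.6},
                              "sm": {("v", "c1"): 1.0, ("v", "c2"): 1.0}})
        ids, p = typed_step_probs(g, "v", rho_value=0.5)
        assert ids == ["a", "b", "c1", "c2"]
        np.testing.assert_allclose(p, [0.3, 0.2, 0.25, 0.25])

    def test_no_metabolite_edges_moves_to_same_type(self, toy_graph):
        ids, p = typed_step_probs(toy_graph, "m3")
        assert ids == ["m1"]
        np.testing.assert_allclose(p, [1.0])

    def test_no_same_type_neighbors_uniform_over_metabolites(self):
        reg = NodeRegistry.build(["v"], ["c1", "c2", "c3"], [])
        g = HeteroGraph(reg, {"sm": {("v", "c1"): 1.0, ("v", "c2"): 1.0,
                                     ("v", "c3"): 1.0}})
        ids, p = typed_step_probs(g, "v")
        np.testing.assert_allclose(p, 1 / 3)

    def test_rejects_metabolite_node(self, toy_graph):
        with pytest.raises(GraphError):
            typed_step_probs(toy_graph, "c1")


class TestDistributionsProperty:
    def test_all_step_laws_are_distributions(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            g = random_hetero_graph(rng)
            M = init_uniform()
            reg = g.registry
            for v in reg.microbes + reg.drugs:
                ids, p = typed_step_probs(g, v)
                if ids:
                    assert p.min() >= 0
                    assert p.sum() == pytest.approx(1.0, abs=1e-9)
            for v in reg.metabolites:
                for u, _, _ in g.neighbors(v):
                    ids, p = metabolite_step_probs(g, M, u, v)
                    if ids:
                        assert p.min() >= 0
                        assert p.sum() == pytest.approx(1.0, abs=1e-9)


class TestCorpus:
    def test_budget_and_lengths(self, toy_graph):
        cfg = WalkConfig(walks_per_node=5, walk_length=10, seed=1)
        corpus = generate_corpus(toy_graph, init_uniform(), cfg)
        assert len(corpus) == 8 * 5
        assert all(1 <= len(s) <= 10 for s in corpus.sentences)

    def test_walks_are_valid_paths(self, toy_graph):
        cfg = WalkConfig(walks_per_node=5, walk_length=10, seed=1)
        corpus = generate_corpus(toy_graph, init_uniform(), cfg)
        for sent in corpus.sentences:
            for a, b in zip(sent, sent[1:]):
                toy_graph.edge_type(a, b)  # raises if not adjacent

    def test_isolated_start_gives_length_one_walk(self, toy_graph):
        cfg = WalkConfig(walks_per_node=2, walk_length=10, seed=1)
        corpus = generate_corpus(toy_graph, init_uniform(), cfg)
        c3_walks = [s for s in corpus.sentences if s[0] == "c3"]
        assert c3_walks and all(s == ["c3"] for s in c3_walks)

    def test_determinism(self, toy_graph):
        cfg = WalkConfig(walks_per_node=10, walk_length=10, seed=9)
        a = generate_corpus(toy_graph, init_uniform(), cfg)
        b = generate_corpus(toy_graph, init_uniform(), cfg)
        assert a.sentences == b.sentences

    def test_save_load_round_trip(self, toy_graph, tmp_path):
        cfg = WalkConfig(walks_per_node=3, walk_length=5, seed=2)
        corpus = generate_corpus(toy_graph, init_uniform(), cfg)
        corpus.save(tmp_path / "corpus.txt")
        from metamda.random_walk import WalkCorpus
        loaded = WalkCorpus.load(tmp_path / "corpus.txt")
        assert loaded.sentences == corpus.sentences
        assert loaded.node_types == corpus.node_types

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WalkConfig(walk_length=1)
        with pytest.raises(ValueError):
            WalkConfig(t=1.5)
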