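"""CoPath core: conservative weights, OIN, weighted matching, paths."""

import random

import pytest

from conftest import best_matching_by_enumeration, random_layer
from copath import (
    DirectedLayer,
    Matching,
    MultilayerNetwork,
    build_oin,
    classify_edges,
    conservative_weights,
    extract_control_paths,
    maximum_matching,
    mwmc_matching,
    restore_critical,
    run_copath,
)
from copath.core import ControlPath


@pytest.fixture
def three_layer_net(toy_layer):
    """Three layers in which edge 2->3 is ordinary-or-critical everywhere:
    two copies of the toy digraph (2->3 ordinary) and a chain 2->3->6
    (2->3 critical)."""
    chain = DirectedLayer("l3", nodes={"2", "3", "6"},
                          edges={("2", "3"), ("3", "6")})
    return MultilayerNetwork(
        layers=[toy_layer.copy("l1"), toy_layer.copy("l2"), chain]
    )


class TestConservativeWeights:
    def test_edge_ordinary_or_critical_in_all_three_layers_has_weight_3(
        self, three_layer_net
    ):
        cls = {l.layer_id: classify_edges(l) for l in three_layer_net.layers}
        w = conservative_weights(three_layer_net, cls)
        assert w[("2", "3")] == 3

    def test_everywhere_redundant_edge_is_absent(self, toy_layer):
        net = MultilayerNetwork(layers=[toy_layer.copy("a"), toy_layer.copy("b")])
        cls = {l.layer_id: classify_edges(l) for l in net.layers}
        w = conservative_weights(net, cls)
        assert ("2", "5") not in w  # redundant in both layers

    def test_matches_naive_membership_count_on_random_layers(self):
        rng = random.Random(11)
        layers = [random_layer(rng).copy(f"L{i}") for i in range(4)]
        net = MultilayerNetwork(layers=layers)
        cls = {l.layer_id: classify_edges(l) for l in layers}
        w = conservative_weights(net, cls)
        all_edges = set().union(*(l.edges for l in layers))
        for e in all_edges:
            naive = sum(
                1 for l in layers
                if e in cls[l.layer_id].ordinary | cls[l.layer_id].critical
            )
            assert w.get(e, 0) == naive

    def test_layer_mismatch_rejected(self, three_layer_net):
        cls = {l.layer_id: classify_edges(l) for l in three_layer_net.layers}
        del cls["l3"]
        with pytest.raises(ValueError, match="layers"):
            conservative_weights(three_layer_net, cls)


class TestBuildOIN:
    def test_oin_contains_exactly_the_ordinary_edges(self, toy_layer):
        cls = classify_edges(toy_layer)
        oin = build_oin(toy_layer, cls, {e: 1 for e in cls.ordinary})
        assert oin.edges == {("2", "3"), ("2", "4")}
        assert oin.bipartite.links[("2", "3")] == (("+", "2"), ("-", "3"))

    def test_layer_with_no_ordinary_edges_gives_empty_oin(self):
        chain = DirectedLayer("c", nodes={"a", "b", "c"},
                              edges={("a", "b"), ("b", "c")})
        cls = classify_edges(chain)
        assert not cls.ordinary
        oin = build_oin(chain, cls, {})
        assert not oin.edges

    def test_missing_weight_rejected(self, toy_layer):
        cls = classify_edges(toy_layer)
        with pytest.raises(ValueError, match="conservative weight"):
            build_oin(toy_layer, cls, {("2", "3"): 1})


class TestMWMCMatching:
    def _oin(self, edges, weights):
        nodes = {n for e in edges for n in e}
        # build the weighted view directly: the oracle treats every edge as
        # matchable, so no classification step here
        from copath.netmodel import BipartiteView, in_copy, out_copy
        view = BipartiteView(
            out_copies={out_copy(u) for u in nodes},
            in_copies={in_copy(v) for v in nodes},
            links={(u, v): (out_copy(u), in_copy(v)) for (u, v) in edges},
        )
        from copath.core import OIN
        return OIN(layer_id="w", bipartite=view, cons_weight=dict(weights))

    def test_single_edge_oin_returns_it(self):
        oin = self._oin([("a", "b")], {("a", "b"): 2})
        assert mwmc_matching(oin).edges == {("a", "b")}

    def test_prefers_heavier_edge_at_equal_cardinality(self):
        oin = self._oin([("a", "b"), ("a", "c")],
                        {("a", "b"): 1, ("a", "c"): 3})
        assert mwmc_matching(oin).edges == {("a", "c")}

    def test_cardinality_beats_weight(self):
        oin = self._oin(
            [("a", "b"), ("a", "c"), ("d", "b")],
            {("a", "b"): 5, ("a", "c"): 1, ("d", "b"): 1},
        )
        assert mwmc_matching(oin).edges == {("a", "c"), ("d", "b")}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cardinality_and_weight_match_brute_force(self, seed):
        rng = random.Random(seed)
        for _ in range(40):
            layer = random_layer(rng)
            if not layer.edges:
                continue
            weights = {e: rng.randint(1, 6) for e in layer.edges}
            oin = self._oin(layer.edges, weights)
            m = mwmc_matching(oin)
            got = (len(m), sum(weights[e] for e in m.edges))
            assert got == best_matching_by_enumeration(layer.edges, weights)

    def test_empty_oin(self):
        assert len(mwmc_matching(self._oin([], {}))) == 0


class TestRestoreCritical:
    def test_toy_restoration_reaches_maximum_cardinality(self, toy_layer):
        cls = classify_edges(toy_layer)
        restored = restore_critical(Matching({("2", "3")}), cls)
        assert restored.edges == {("1", "2"), ("2", "3"), ("4", "5")}
        assert len(restored) == len(maximum_matching(toy_layer))

    def test_empty_plus_empty_is_empty(self):
        from copath.controllability import EdgeClassification
        assert len(restore_critical(Matching(set()), EdgeClassification())) == 0

    def test_redundant_edges_in_input_rejected(self, toy_layer):
        cls = classify_edges(toy_layer)
        with pytest.raises(ValueError, match="redundant"):
            restore_critical(Matching({("2", "5")}), cls)

    def test_restored_matching_is_maximum_on_random_layers(self):
        rng = random.Random(21)
        for _ in range(40):
            layer = random_layer(rng)
            cls = classify_edges(layer)
            oin = build_oin(layer, cls, {e: 1 for e in cls.ordinary})
            restored = restore_critical(mwmc_matching(oin), cls)
            assert len(restored) == len(maximum_matching(layer))


class TestExtractControlPaths:
    def test_toy_matching_gives_two_stems(self, toy_layer):
        m = Matching({("1", "2"), ("2", "3"), ("4", "5")})
        paths = extract_control_paths(toy_layer, m)
        assert [(p.kind, p.nodes) for p in paths] == [
            ("stem", ["1", "2", "3"]),
            ("stem", ["4", "5"]),
        ]
        assert paths[0].root == "1"

    def test_two_cycle(self):
        layer = DirectedLayer("c", nodes={"1", "2"},
                              edges={("1", "2"), ("2", "1")})
        paths = extract_control_paths(layer, maximum_matching(layer))
        assert len(paths) == 1
        assert paths[0].kind == "cycle"
        assert set(paths[0].edges) == {("1", "2"), ("2", "1")}

    def test_edge_conservation_and_stem_count_on_random_matchings(self):
        rng = random.Random(33)
        for _ in range(40):
            layer = random_layer(rng)
            m = maximum_matching(layer)
            paths = extract_control_paths(layer, m)
            edges = [e for p in paths for e in p.edges]
            assert sorted(edges) == sorted(m.edges)  # each edge exactly once
            n_stems = sum(1 for p in paths if p.kind == "stem")
            assert n_stems == len(m.tails - m.heads)

    def test_stem_has_one_fewer_edge_than_nodes(self):
        cp = ControlPath(nodes=["a", "b", "c"], kind="stem")
        assert len(cp.edges) == len(cp) - 1


class TestRunCoPath:
    def test_single_layer_cv_is_one(self, toy_layer):
        result = run_copath(MultilayerNetwork(layers=[toy_layer]))
        assert result.cv == 1.0

    def test_identical_layers_share_matchings_and_cv_is_one(self, toy_layer):
        net = MultilayerNetwork(
            layers=[toy_layer.copy(f"c{i}") for i in range(4)]
        )
        result = run_copath(net)
        edge_sets = {frozenset(m.edges)
                     for m in result.per_layer_matchings.values()}
        assert len(edge_sets) == 1
        assert result.cv == 1.0

    @pytest.mark.parametrize("L", [2, 3, 5])
    def test_node_disjoint_layers_reach_cv_floor(self, L):
        layers = [
            DirectedLayer(f"d{i}", nodes={f"{i}a", f"{i}b"},
                          edges={(f"{i}a", f"{i}b")})
            for i in range(L)
        ]
        result = run_copath(MultilayerNetwork(layers=layers))
        assert result.cv == pytest.approx((1 / L) ** 2)

    def test_no_redundant_edges_in_output_and_counts_conserve(self, three_layer_net):
        result = run_copath(three_layer_net)
        for lid, m in result.per_layer_matchings.items():
            cls = result.per_layer_classifications[lid]
            assert not (m.edges & cls.redundant)
        assert sum(len(m) for m in result.per_layer_matchings.values()) == \
               sum(result.layer_counts.values())
        for lid, m in result.per_layer_matchings.items():
            path_edges = sum(
                len(p.edges) for p in result.per_layer_paths[lid]
            )
            assert path_edges == len(m)

    def test_conserved_edge_chosen_in_every_layer(self, three_layer_net):
        # 2->3 carries conservative weight 3: every layer's matching takes it
        result = run_copath(three_layer_net)
        assert all(("2", "3") in m.edges
                   for m in result.per_layer_matchings.values())
        assert result.layer_counts[("2", "3")] == 3

    def test_repeated_runs_identical(self, three_layer_net):
        r1 = run_copath(three_layer_net)
        r2 = run_copath(three_layer_net)
        assert r1.cv == r2.cv
        assert {k: m.edges for k, m in r1.per_layer_matchings.items()} == \
               {k: m.edges for k, m in r2.per_layer_matchings.items()}
        assert [(p.kind, p.nodes) for ps in r1.per_layer_paths.values() for p in ps] == \
               [(p.kind, p.nodes) for ps in r2.per_layer_paths.values() for p in ps]
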