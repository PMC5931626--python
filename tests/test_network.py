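"""Graph predicates: routes, circuits, pruning, regulators, dependents."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from rpatopo.network import (Network, NetworkError, NoRouteError, Regulation,
                             brute_force_circuits, brute_force_routes,
                             circuit_route_relation, dependents,
                             enumerate_circuits, enumerate_routes,
                             independent_regulators, validate_and_prune)

from conftest import complete_digraph, random_network


class TestConstruction:
    def test_self_regulation_rejected(self):
        with pytest.raises(NetworkError, match="implicit"):
            Regulation("A", "A")

    def test_duplicate_edge_rejected(self):
        with pytest.raises(NetworkError, match="duplicate regulation"):
            Network.from_edges([("A", "B"), ("A", "B", "inhibiting")],
                               "A", "B")

    def test_dangling_ids_rejected(self):
        with pytest.raises(NetworkError, match="undeclared"):
            Network(("A", "B"), (Regulation("A", "Z"),), "A", "B")
        with pytest.raises(NetworkError, match="input"):
            Network(("A", "B"), (Regulation("A", "B"),), "Q", "B")

    def test_unknown_sign_rejected(self):
        with pytest.raises(NetworkError, match="sign"):
            Regulation("A", "B", "mystery")


class TestPruning:
    def test_isolated_node_removed(self):
        net = Network.from_edges([("I", "A"), ("A", "O")], "I", "O",
                                 nodes=["I", "A", "O", "Z"])
        pruned, removed = validate_and_prune(net)
        assert removed == ("Z",)
        assert set(pruned.nodes) == {"A", "I", "O"}

    def test_fig2b_wiring_unchanged(self, fig2b_net):
        pruned, removed = validate_and_prune(fig2b_net)
        assert removed == ()
        assert pruned == fig2b_net

    def test_unreachable_cycle_removed(self):
        # cycle x<->y feeds the route but is fed by nothing on any route,
        # and shares no node with a route: removed
        net = Network.from_edges(
            [("I", "A"), ("A", "O"), ("x", "y"), ("y", "x"), ("x", "O")],
            "I", "O")
        pruned, removed = validate_and_prune(net)
        assert removed == ("x", "y")

    def test_contiguous_circuit_kept(self, fig2a_net):
        pruned, removed = validate_and_prune(fig2a_net)
        assert removed == ()
        assert set(pruned.nodes) == {"O", "X"}

    def test_chained_circuits_kept(self):
        # circuit (A,B) touches the route; circuit (B,C2) touches (A,B)
        net = Network.from_edges(
            [("I", "A"), ("A", "O"), ("A", "B"), ("B", "A"),
             ("B", "C2"), ("C2", "B")], "I", "O")
        pruned, removed = validate_and_prune(net)
        assert removed == ()

    def test_no_route_error(self):
        net = Network.from_edges([("O", "I")], "I", "O")
        with pytest.raises(NoRouteError):
            validate_and_prune(net)

    def test_idempotent_and_route_preserving(self):
        rng = random.Random(11)
        for _ in range(50):
            net = random_network(rng)
            if net is None:
                continue
            try:
                once, _ = validate_and_prune(net)
            except NoRouteError:
                continue
            twice, removed2 = validate_and_prune(once)
            assert removed2 == ()
            assert twice == once
            route_nodes = {n for r in enumerate_routes(net) for n in r}
            assert route_nodes <= set(once.nodes)


class TestRoutesAndCircuits:
    def test_chain_route(self):
        net = Network.from_edges([("I", "A"), ("A", "O")], "I", "O")
        assert enumerate_routes(net) == [("I", "A", "O")]

    def test_fig2b_routes(self, fig2b_net):
        assert enumerate_routes(fig2b_net) == [("D", "B", "C"), ("D", "C")]

    def test_single_node_route_when_io_coincide(self, fig2a_net):
        assert enumerate_routes(fig2a_net) == [("X",)]

    def test_complete_digraph_route_count(self):
        # sum over k of P(n-2, k) simple paths through intermediates
        assert len(enumerate_routes(complete_digraph(5))) == 16

    def test_fig2a_single_circuit(self, fig2a_net):
        assert enumerate_circuits(fig2a_net) == [("O", "X")]

    def test_acyclic_chain_no_circuits(self, fig2b_net):
        assert enumerate_circuits(fig2b_net) == []

    def test_complete_digraph_circuit_count(self):
        # C(4,2) 2-cycles + 2*C(4,3) 3-cycles + 6 hamiltonian = 20
        assert len(enumerate_circuits(complete_digraph(4))) == 20

    def test_matches_brute_force_on_random_networks(self):
        rng = random.Random(7)
        checked = 0
        while checked < 60:
            net = random_network(rng, n_max=7)
            if net is None:
                continue
            checked += 1
            assert enumerate_routes(net) == brute_force_routes(net)
            assert enumerate_circuits(net) == brute_force_circuits(net)

    def test_canonical_rotation(self):
        net = Network.from_edges([("b", "c"), ("c", "a"), ("a", "b")],
                                 "a", "a")
        (circ,) = enumerate_circuits(net)
        assert circ == ("a", "b", "c")


@st.composite
def small_digraphs(draw, n_max: int = 5):
    n = draw(st.integers(2, n_max))
    nodes = [f"n{i}" for i in range(n)]
    pairs = [(a, b) for a, b in itertools.permutations(nodes, 2)]
    mask = draw(st.lists(st.booleans(), min_size=len(pairs),
                         max_size=len(pairs)))
    edges = [p for p, keep in zip(pairs, mask) if keep]
    out = draw(st.sampled_from(nodes))
    return Network.from_edges(edges, "n0", out, nodes=nodes)


class TestEnumerationProperties:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(small_digraphs())
    def test_routes_and_circuits_agree_with_depth_first_search(self, net):
        assert enumerate_routes(net) == brute_force_routes(net)
        assert enumerate_circuits(net) == brute_force_circuits(net)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(small_digraphs())
    def test_prune_keeps_routes_and_is_idempotent(self, net):
        try:
            pruned, _ = validate_and_prune(net)
        except NoRouteError:
            assert enumerate_routes(net) == [] or net.input != net.output
            return
        assert {n for r in enumerate_routes(net) for n in r} <= set(
            pruned.nodes)
        assert validate_and_prune(pruned) == (pruned, ())


class TestCircuitRouteRelation:
    def test_contiguous_single_node_route(self, fig2a_net):
        assert circuit_route_relation(("O", "X"), ("X",)) == "contiguous"

    def test_disjoint(self):
        assert circuit_route_relation(("a", "b"), ("c", "d")) == "disjoint"

    def test_dichotomy_on_random_pairs(self):
        rng = random.Random(3)
        for _ in range(40):
            net = random_network(rng)
            if net is None:
                continue
            for c in enumerate_circuits(net):
                for r in enumerate_routes(net):
                    rel = circuit_route_relation(c, r)
                    assert rel == ("contiguous" if set(c) & set(r)
                                   else "disjoint")


class TestRegulatorsAndDependents:
    def test_fig2a_output_regulator(self, fig2a_net):
        assert independent_regulators(fig2a_net, {"O"}) == ["X"]

    def test_fig2b_balancer_regulator(self, fig2b_net):
        assert independent_regulators(fig2b_net, {"B"}) == ["D"]

    def test_whole_network_has_none(self, fig2b_net):
        assert independent_regulators(fig2b_net, set(fig2b_net.nodes)) == []

    def test_empty_set_rejected(self, fig2a_net):
        with pytest.raises(ValueError):
            independent_regulators(fig2a_net, set())

    def test_dependents_full_closure(self):
        net = Network.from_edges([("A", "B"), ("A", "C"), ("B", "C")],
                                 "A", "C")
        assert dependents(net, {"A"}) == {"B", "C"}

    def test_dependents_blocked_by_outside_regulator(self):
        net = Network.from_edges([("A", "B"), ("Z", "B"), ("Z", "A")],
                                 "Z", "B")
        assert dependents(net, {"A"}) == set()

    def test_dependents_disjoint_and_monotone(self):
        rng = random.Random(13)
        for _ in range(40):
            net = random_network(rng)
            if net is None:
                continue
            nodes = list(net.nodes)
            s1 = {nodes[0]}
            s2 = set(nodes[: max(1, len(nodes) // 2)])
            d1, d2 = dependents(net, s1), dependents(net, s2)
            assert d1 & s1 == set()
            assert d1 | s1 <= d2 | s2

    def test_dependents_agree_with_ancestor_oracle_on_dags(self):
        # in a DAG, u depends on S iff every maximal ancestor chain of u
        # enters S; brute-force check on small random DAGs
        rng = random.Random(5)
        for _ in range(30):
            n = rng.randint(3, 6)
            nodes = [f"n{i}" for i in range(n)]
            edges = [(nodes[i], nodes[j]) for i in range(n)
                     for j in range(i + 1, n) if rng.random() < 0.5]
            if not edges:
                continue
            net = Network.from_edges(edges, nodes[0], nodes[-1],
                                     nodes=nodes)
            S = {nodes[0]}
            expected = set()
            changed = True
            while changed:
                changed = False
                for u in nodes:
                    if u in S | expected:
                        continue
                    regs = net.regulators_of(u)
                    if regs and set(regs) <= S | expected:
                        expected.add(u)
                        changed = True
            assert dependents(net, S) == expected
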