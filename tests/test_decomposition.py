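"""Opposer/balancer detection and decomposition enumeration."""

import pytest

from rpatopo.decomposition import (classify_outgoing_regulations,
                                   enumerate_decompositions,
                                   find_balancer_modules,
                                   find_opposer_modules, find_opposing_sets,
                                   opposer_candidates,
                                   routes_fully_opposed_by,
                                   routes_partially_opposed_by, rpa_nodes)
from rpatopo.fixtures import paper_fixture
from rpatopo.network import Network, enumerate_routes


class TestOpposerCandidates:
    def test_fig2a_opposer(self, fig2a_net):
        assert "O" in opposer_candidates(fig2a_net)

    def test_acyclic_chain_has_none(self, fig2b_net):
        assert opposer_candidates(fig2b_net) == []

    def test_junction_of_two_loops_excluded(self):
        # v sits in two node-disjoint cycles and has two regulators
        net = Network.from_edges(
            [("I", "v"), ("v", "I"), ("v", "w"), ("w", "v"), ("v", "O"),
             ("I", "O")], "I", "O")
        assert "v" not in opposer_candidates(net)
        assert "w" in opposer_candidates(net)


class TestRouteOpposition:
    def test_routes_fully_opposed_fig6(self):
        net = paper_fixture("fig6").network
        full = routes_fully_opposed_by(net, "10")
        # every route avoiding node 10 is opposed via the contiguous (2,10)
        assert full == [r for r in enumerate_routes(net) if "10" not in r]

    def test_route_containing_opposer_not_opposed(self):
        net = paper_fixture("fig6").network
        for r in routes_fully_opposed_by(net, "10"):
            assert "10" not in r

    def test_partial_opposition_with_disjoint_circuit(self):
        net = paper_fixture("fig8b").network
        # opposer 3's circuit (3,5) is disjoint from route [1,4,6]
        assert ("1", "4", "6") in routes_partially_opposed_by(net, "3")
        assert ("1", "4", "6") not in routes_fully_opposed_by(net, "3")

    def test_non_candidate_rejected(self, fig2b_net):
        with pytest.raises(ValueError):
            routes_fully_opposed_by(fig2b_net, "B")


class TestOpposingSets:
    def test_fig2a_trivial_set(self, fig2a_net):
        sets = find_opposing_sets(fig2a_net, ("X",))
        assert any(s.opposers == frozenset({"O"})
                   and s.master_set == frozenset({"O"}) for s in sets)

    def test_fig3a_two_node_set_with_master(self):
        net = paper_fixture("fig3a").network
        sets = find_opposing_sets(net, ("P1", "P2"))
        match = [s for s in sets if s.opposers == frozenset({"O1", "O2"})]
        assert match and match[0].master_set == frozenset({"O1", "X", "O2"})

    def test_antithetic_two_node_set_single_io(self):
        net = paper_fixture("antithetic").network
        sets = find_opposing_sets(net, ("X",))
        assert any(s.opposers == frozenset({"Z1", "Z2"}) for s in sets)

    def test_fig3c_three_opposer_chain(self):
        net = paper_fixture("fig3c").network
        sets = find_opposing_sets(net, ("P1", "P2"))
        match = [s for s in sets
                 if s.opposers == frozenset({"O1", "O2", "O3"})]
        assert match
        assert match[0].master_set == frozenset(
            {"O1", "X1", "O2", "X2", "O3"})


class TestBalancerModules:
    def test_fig2b_module(self, fig2b_net):
        (mod,) = find_balancer_modules(fig2b_net)
        assert mod.diverter == "D"
        assert mod.connector == "C"
        assert mod.balancers == frozenset({"B"})

    def test_single_io_node_has_none(self, fig2a_net):
        assert find_balancer_modules(fig2a_net) == []

    def test_double_chain(self):
        net = Network.from_edges(
            [("D", "B1"), ("B1", "C"), ("D", "B2"), ("B2", "C")], "D", "C")
        (mod,) = find_balancer_modules(net)
        assert mod.balancers == frozenset({"B1", "B2"})
        assert len(mod.balanced_routes) == 2

    def test_diverter_balancer_feedback_rejected(self):
        # a 2-cycle between the would-be diverter and a balancer is not a
        # fully embedded loop: no module may claim it
        net = Network.from_edges(
            [("D", "B"), ("B", "D"), ("B", "C"), ("D", "C")], "D", "C")
        assert find_balancer_modules(net) == []

    def test_embedded_loop_absorbed(self):
        net = paper_fixture("fig8b").network
        mods = find_balancer_modules(net)
        big = [m for m in mods if m.connector == "6"]
        assert big and big[0].balancers == frozenset({"2", "3", "4", "5"})
        assert big[0].embedded_circuits == frozenset({("3", "5")})


class TestRegulationClasses:
    def test_opposer_live_and_regulator_blind(self):
        net = paper_fixture("fig6").network
        module = next(m for m in find_opposer_modules(net)
                      if m.opposers == frozenset({"10"}))
        classes = classify_outgoing_regulations(net, module)
        assert classes[("10", "3")] == "live"
        assert classes[("2", "11")] == "blind"
        assert classes[("2", "3")] == "blind"

    def test_connector_blind_balancer_live(self):
        net = paper_fixture("fig6").network
        module = next(m for m in find_balancer_modules(net)
                      if m.diverter == "3")
        classes = classify_outgoing_regulations(net, module)
        # connector 13 is the output: no outgoing edges; balancers have no
        # extramodular edges in this wiring, diverter 3 none either
        assert all(v in {"live", "blind"} for v in classes.values())

    def test_balancer_live_regulation_fig8b(self):
        net = paper_fixture("fig8b").network
        module = next(m for m in find_balancer_modules(net)
                      if m.connector == "4")
        classes = classify_outgoing_regulations(net, module)
        assert classes[("2", "5")] == "live"
        assert classes[("4", "6")] == "blind"


class TestDecompositions:
    def test_fig6_unique_series_decomposition(self):
        net = paper_fixture("fig6").network
        decomps = enumerate_decompositions(net)
        assert len(decomps) == 1
        kinds = sorted(m.kind for m in decomps[0].modules)
        assert kinds == ["balancer", "opposer"]
        assert decomps[0].series_links  # opposer feeds the balancer

    def test_fig7_contains_both_solutions(self):
        net = paper_fixture("fig7").network
        decomps = enumerate_decompositions(net)
        assert len(decomps) >= 2
        sol1 = [d for d in decomps if len(d.modules) == 2 and any(
            m.kind == "opposer" and m.opposers == frozenset({"6"})
            for m in d.modules) and any(
            m.kind == "balancer" and m.balancers == frozenset({"9", "10"})
            and m.connector == "11" for m in d.modules)]
        sol2 = [d for d in decomps if len(d.modules) == 1
                and d.modules[0].kind == "opposer"
                and d.modules[0].opposers == frozenset({"7"})]
        assert sol1 and sol2

    def test_feedforward_chain_not_capable(self):
        net = Network.from_edges([("I", "A"), ("A", "O")], "I", "O")
        assert enumerate_decompositions(net) == []

    def test_route_coverage_partition(self):
        for name in ["fig2a", "fig2b", "fig6", "fig7", "fig8a", "fig8e"]:
            net = paper_fixture(name).network
            routes = enumerate_routes(net)
            for d in enumerate_decompositions(net):
                assert set(d.route_assignment) == set(routes)

    def test_no_balancer_when_io_coincide(self):
        for name in ["fig2a", "antithetic"]:
            net = paper_fixture(name).network
            for d in enumerate_decompositions(net):
                assert all(m.kind == "opposer" for m in d.modules)

    def test_kinetics_roles_mutually_exclusive(self):
        for name in ["fig6", "fig7", "fig8e", "fig8f"]:
            net = paper_fixture(name).network
            for d in enumerate_decompositions(net):
                seen = set()
                for m in d.modules:
                    roles = m.role_nodes()
                    assert not roles & seen
                    seen |= roles


class TestRPANodes:
    def test_fig2a_regulator_not_opposer(self, fig2a_net):
        (d,) = enumerate_decompositions(fig2a_net)
        assert rpa_nodes(d) == {"X"}

    def test_fig2b_connector_only(self, fig2b_net):
        (d,) = enumerate_decompositions(fig2b_net)
        assert rpa_nodes(d) == {"C"}

    def test_fig3c_chain_marks(self):
        net = paper_fixture("fig3c").network
        decomps = enumerate_decompositions(net)
        chain = [d for d in decomps if len(d.modules) == 1 and
                 d.modules[0].kind == "opposer" and
                 d.modules[0].opposers == frozenset({"O1", "O2", "O3"})]
        assert chain
        assert rpa_nodes(chain[0]) == {"X1", "X2", "P2"}

    def test_fig7_sol2_all_but_input_and_opposer(self):
        net = paper_fixture("fig7").network
        sol2 = [d for d in enumerate_decompositions(net)
                if len(d.modules) == 1
                and d.modules[0].opposers == frozenset({"7"})]
        assert rpa_nodes(sol2[0]) == set(net.nodes) - {"1", "7"}

    def test_output_always_marked(self):
        for name in ["fig2a", "fig2b", "fig6", "fig7", "fig8a", "fig8b",
                     "fig8c", "fig8e", "fig8f", "antithetic", "fig3a"]:
            net = paper_fixture(name).network
            for d in enumerate_decompositions(net):
                assert net.output in rpa_nodes(d)
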