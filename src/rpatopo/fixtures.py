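"""Built-in model fixtures: the worked figure models and reference motifs.

``fig2a`` and ``fig2b`` use the caption-printed equations and parameters
verbatim.  The remaining fixtures are canonical reconstructions: the source
figures describe node roles (which nodes carry opposer/balancer/connector
kinetics, which exhibit RPA) without printing edge lists or equations, so
each builder documents the assumed wiring and uses rate constants chosen for
positivity and stability.  Negative-control variants (``*_noloop``,
``*_nonlinear``) deliberately break one structural requirement.

Every fixture returns a :class:`Model`; ``model.system()`` yields the
simulatable ODE system and ``model.network`` feeds the topological analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import ODESystem, make_rate_law
from .network import Network

__all__ = ["Model", "paper_fixture", "fixture_names"]


@dataclass(frozen=True)
class Model:
    name: str
    network: Network
    laws: dict
    notes: str = ""

    def system(self) -> ODESystem:
        return ODESystem(self.network, self.laws)

    def kinetics_assignment(self) -> dict:
        return {n: law.kinetics_class for n, law in sorted(self.laws.items())}


def _law(net: Network, node: str, cls: str, params: dict, **kw):
    regs = [(s, net.sign_of(s, node)) for s in net.regulators_of(node)]
    return make_rate_law(node, cls, regs, params,
                         stimulus=(node == net.input), **kw)


# ---------------------------------------------------------------------------
# minimal worked models
# ---------------------------------------------------------------------------

def _fig2a() -> Model:
    """Minimal opposer module: X (input = output) under feedback from the
    opposer O.  dX/dt = k3*(I/O) - k4*X, dO/dt = k1*X - k2;
    k1 = k4 = 1, k2 = 0.5, k3 = 0.4, so X* = k2/k1 = 0.5 for every I."""
    net = Network.from_edges(
        [("X", "O", "activating"), ("O", "X", "inhibiting")], "X", "X")
    laws = {
        "X": _law(net, "X", "generic", {"kp": 0.4, "kd": 1.0}),
        "O": _law(net, "O", "opposer", {"ka": 1.0, "kb": 0.5}),
    }
    return Model("fig2a", net, laws, "minimal opposer module")


def _fig2a_noloop() -> Model:
    """Negative control: the O->X feedback edge removed.  O no longer
    participates in a circuit, so no opposer structure exists and X* tracks
    the input (the opposer equation has no steady state)."""
    net = Network.from_edges([("X", "O", "activating")], "X", "X")
    laws = {
        "X": _law(net, "X", "generic", {"kp": 0.4, "kd": 1.0}),
        "O": _law(net, "O", "opposer", {"ka": 1.0, "kb": 0.5}),
    }
    return Model("fig2a_noloop", net, laws, "feedback deleted: no RPA")


def _fig2b() -> Model:
    """Minimal balancer module (incoherent feedforward): D -> B -> C with
    direct D -> C.  dD/dt = k5*I - k6*D, dB/dt = k1*D - k2*B,
    dC/dt = k3*B - k4*D*C; k2 = k4 = k5 = k6 = 1, k1 = 0.8, k3 = 0.5, so
    C* = k1*k3/(k2*k4) = 0.4 for every I."""
    net = Network.from_edges(
        [("D", "B", "activating"), ("B", "C", "activating"),
         ("D", "C", "inhibiting")], "D", "C")
    laws = {
        "D": _law(net, "D", "generic", {"kp": 1.0, "kd": 1.0}),
        "B": _law(net, "B", "balancer", {"kb1": 0.8, "kb2": 1.0}),
        "C": _law(net, "C", "connector", {"kc1": 0.5, "kc2": 1.0}),
    }
    return Model("fig2b", net, laws, "minimal balancer module")


def _fig2b_nonlinear() -> Model:
    """Negative control: balancer de-linearized (quadratic removal), so B*
    is no longer a linear function of D* and the balancing act fails."""
    base = _fig2b()
    laws = dict(base.laws)
    net = base.network
    laws["B"] = _law(net, "B", "balancer", {"kb1": 0.8, "kb2": 1.0},
                     form="quadratic_removal")
    return Model("fig2b_nonlinear", net, laws, "flat manifold broken: no RPA")


def _antithetic() -> Model:
    """Antithetic integral feedback: Z1/Z2 mutual annihilation around X
    (single input/output node).  dX/dt = k1*I*Z1 - k2*X,
    dZ1/dt = mu - eta*Z1*Z2, dZ2/dt = theta*X - eta*Z2*Z1, giving
    X* = mu/theta.  Topologically a two-node opposing set {Z1, Z2}."""
    net = Network.from_edges(
        [("Z1", "X", "activating"), ("X", "Z2", "activating"),
         ("Z1", "Z2", "inhibiting"), ("Z2", "Z1", "inhibiting")], "X", "X")
    laws = {
        "X": _law(net, "X", "generic", {"kp": 1.0, "kd": 1.0}),
        "Z1": _law(net, "Z1", "opposer", {"ka": 0.5, "kb": 1.0},
                   form="annihilation"),
        "Z2": _law(net, "Z2", "opposer", {"ka": 1.0, "kb": 1.0},
                   form="annihilation"),
    }
    return Model("antithetic", net, laws, "antithetic integral feedback")


# ---------------------------------------------------------------------------
# opposing-set chains
# ---------------------------------------------------------------------------

def _fig3a() -> Model:
    """Two-node opposing set {O1, O2} with master set {O1, X, O2}.

    Assumed wiring: route P1 -> P2; disjoint 2-cycles (O1, X) and (X, O2);
    P2 <-> O2 feedback embeds the set.  O1 tracks X (X* fixed); O2 tracks
    the X--P2 relation, imparting RPA to the output P2."""
    net = Network.from_edges(
        [("P1", "P2", "activating"),
         ("X", "O1", "activating"), ("O1", "X", "inhibiting"),
         ("X", "O2", "inhibiting"), ("O2", "X", "activating"),
         ("P2", "O2", "activating"), ("O2", "P2", "inhibiting")],
        "P1", "P2")
    laws = {
        "P1": _law(net, "P1", "generic", {"kp": 1.0, "kd": 1.0}),
        "P2": _law(net, "P2", "generic", {"kp": 1.0, "kd": 1.0}),
        "O1": _law(net, "O1", "opposer", {"ka": 1.0, "kb": 0.6}),
        "O2": _law(net, "O2", "opposer", {"ka": 1.0, "kb": 1.0}),
        "X": _law(net, "X", "generic", {"kp": 1.0, "kd": 1.0}),
    }
    return Model("fig3a", net, laws, "two-node opposing set")


def _fig3b() -> Model:
    """Two-node opposing set with the larger master set
    {O1, A, B, C, D, E, O2}: triangle (A, O1, B) interlinked through B with
    the 5-cycle (B, C, D2, E, O2).  O1 pins A; the B -> C -> D2 -> E chain
    inherits RPA; O2 tracks the E--P2 relation."""
    net = Network.from_edges(
        [("P1", "P2", "activating"), ("P2", "O2", "activating"),
         ("O2", "P2", "inhibiting"),
         ("A", "O1", "activating"), ("O1", "B", "activating"),
         ("B", "A", "inhibiting"),
         ("B", "C", "activating"), ("C", "D2", "activating"),
         ("D2", "E", "activating"), ("E", "O2", "inhibiting"),
         ("O2", "B", "activating")],
        "P1", "P2")
    laws = {
        "P1": _law(net, "P1", "generic", {"kp": 1.0, "kd": 1.0}),
        "P2": _law(net, "P2", "generic", {"kp": 1.0, "kd": 1.0}),
        "O1": _law(net, "O1", "opposer", {"ka": 0.1, "kb": 0.05}),
        "O2": _law(net, "O2", "opposer", {"ka": 0.05, "kb": 0.05}),
        "A": _law(net, "A", "generic", {"kp": 0.25, "kd": 1.0}),
        "B": _law(net, "B", "generic", {"kp": 1.0, "kd": 1.0}),
        "C": _law(net, "C", "generic", {"kp": 3.0, "kd": 3.0}),
        "D2": _law(net, "D2", "generic", {"kp": 3.0, "kd": 3.0}),
        "E": _law(net, "E", "generic", {"kp": 3.0, "kd": 3.0}),
    }
    return Model("fig3b", net, laws, "opposing set with 7-node master set")


def _fig3c() -> Model:
    """Chain of three opposers {O1, O2, O3}, master set
    {O1, X1, O2, X2, O3}: each O_i tracks the next X relation, so X1, X2 and
    the output P2 exhibit RPA."""
    net = Network.from_edges(
        [("P1", "P2", "activating"),
         ("X1", "O1", "activating"), ("O1", "X1", "inhibiting"),
         ("X1", "O2", "inhibiting"), ("O2", "X1", "activating"),
         ("X2", "O2", "activating"), ("O2", "X2", "inhibiting"),
         ("X2", "O3", "inhibiting"), ("O3", "X2", "activating"),
         ("P2", "O3", "activating"), ("O3", "P2", "inhibiting")],
        "P1", "P2")
    laws = {
        "P1": _law(net, "P1", "generic", {"kp": 1.0, "kd": 1.0}),
        "P2": _law(net, "P2", "generic", {"kp": 1.0, "kd": 1.0}),
        "O1": _law(net, "O1", "opposer", {"ka": 1.0, "kb": 0.5}),
        "O2": _law(net, "O2", "opposer", {"ka": 1.0, "kb": 1.0}),
        "O3": _law(net, "O3", "opposer", {"ka": 1.0, "kb": 1.0}),
        "X1": _law(net, "X1", "generic", {"kp": 1.0, "kd": 1.0}),
        "X2": _law(net, "X2", "generic", {"kp": 1.0, "kd": 1.0}),
    }
    return Model("fig3c", net, laws, "three-opposer chain")


# ---------------------------------------------------------------------------
# multimodular networks
# ---------------------------------------------------------------------------

def _fig6_network() -> Network:
    return Network.from_edges(
        [("1", "2", "activating"), ("2", "3", "activating"),
         ("2", "10", "activating"), ("10", "2", "inhibiting"),
         ("10", "3", "activating"),
         ("3", "4", "activating"), ("4", "5", "activating"),
         ("5", "13", "activating"),
         ("3", "6", "activating"), ("6", "7", "activating"),
         ("7", "8", "activating"), ("8", "13", "inhibiting"),
         ("2", "11", "activating"), ("11", "12", "activating"),
         ("12", "13", "activating")],
        "1", "13")


def _fig6() -> Model:
    """Opposer module (opposer node 10) in series with a balancer module
    (diverter 3, balancers 4-8 on two branches, connector 13 = output).
    Node 10's live regulation enters the route at node 3; the blind chain
    2 -> 11 -> 12 -> 13 descends from the RPA node 2."""
    net = _fig6_network()
    g = {"kp": 1.0, "kd": 1.0}
    laws = {
        "1": _law(net, "1", "generic", dict(g)),
        "2": _law(net, "2", "generic", dict(g)),
        "10": _law(net, "10", "opposer", {"ka": 1.0, "kb": 0.5}),
        "3": _law(net, "3", "generic", dict(g)),
        "4": _law(net, "4", "balancer", {"kb1": 0.8, "kb2": 1.0}),
        "5": _law(net, "5", "balancer", {"kb1": 1.0, "kb2": 1.0}),
        "6": _law(net, "6", "balancer", {"kb1": 0.6, "kb2": 1.0}),
        "7": _law(net, "7", "balancer", {"kb1": 1.0, "kb2": 1.0}),
        "8": _law(net, "8", "balancer", {"kb1": 1.0, "kb2": 1.0}),
        "11": _law(net, "11", "generic", dict(g)),
        "12": _law(net, "12", "generic", dict(g)),
        "13": _law(net, "13", "connector", {"kc1": 0.5, "kc2": 1.0}),
    }
    return Model("fig6", net, laws, "series opposer -> balancer, 13 nodes")


def _fig7_network() -> Network:
    return Network.from_edges(
        [("1", "2", "activating"), ("2", "3", "activating"),
         ("3", "4", "activating"), ("4", "5", "activating"),
         ("5", "12", "activating"),
         ("2", "6", "activating"), ("6", "2", "inhibiting"),
         ("6", "8", "activating"),
         ("8", "9", "activating"), ("9", "11", "activating"),
         ("8", "10", "activating"), ("10", "11", "inhibiting"),
         ("11", "12", "activating"),
         ("12", "7", "activating"), ("7", "2", "inhibiting")],
        "1", "12")


def _fig7_sol1() -> Model:
    """Solution 1 kinetics for the dual-decomposition topology: opposer at
    node 6 (upstream module) in series with the balancer module
    {D = 8, balancers 9/10, connector 11}."""
    net = _fig7_network()
    g = {"kp": 1.0, "kd": 1.0}
    laws = {
        "1": _law(net, "1", "generic", dict(g)),
        "2": _law(net, "2", "generic", dict(g)),
        "3": _law(net, "3", "generic", dict(g)),
        "4": _law(net, "4", "generic", dict(g)),
        "5": _law(net, "5", "generic", dict(g)),
        "6": _law(net, "6", "opposer", {"ka": 1.0, "kb": 0.5}),
        "7": _law(net, "7", "generic", dict(g)),
        "8": _law(net, "8", "generic", dict(g)),
        "9": _law(net, "9", "balancer", {"kb1": 0.8, "kb2": 1.0}),
        "10": _law(net, "10", "balancer", {"kb1": 0.6, "kb2": 1.0}),
        "11": _law(net, "11", "connector", {"kc1": 0.5, "kc2": 1.0}),
        "12": _law(net, "12", "generic", dict(g)),
    }
    return Model("fig7_sol1", net, laws, "opposer 6 + balancer 9-11")


def _fig7_sol2() -> Model:
    """Solution 2 kinetics for the same topology: opposer at node 7 creates
    a single opposer module; every node except 1 and 7 exhibits RPA."""
    net = _fig7_network()
    g = {"kp": 1.0, "kd": 1.0}
    laws = {n: _law(net, n, "generic", dict(g))
            for n in net.nodes if n != "7"}
    laws["7"] = _law(net, "7", "opposer", {"ka": 1.0, "kb": 0.4})
    return Model("fig7_sol2", net, laws, "single opposer at node 7")


# ---------------------------------------------------------------------------
# small networks combining the new topological features
# ---------------------------------------------------------------------------

def _fig8a() -> Model:
    """Opposer (node 3) whose live regulation feeds the diverter of a
    downstream balancer module (D = 4, balancer 5, connector 6)."""
    net = Network.from_edges(
        [("1", "2", "activating"), ("2", "3", "activating"),
         ("3", "2", "inhibiting"), ("3", "4", "activating"),
         ("4", "5", "activating"), ("5", "6", "activating"),
         ("4", "6", "inhibiting"), ("2", "6", "activating")],
        "1", "6")
    g = {"kp": 1.0, "kd": 1.0}
    laws = {
        "1": _law(net, "1", "generic", dict(g)),
        "2": _law(net, "2", "generic", dict(g)),
        "3": _law(net, "3", "opposer", {"ka": 1.0, "kb": 0.5}),
        "4": _law(net, "4", "generic", dict(g)),
        "5": _law(net, "5", "balancer", {"kb1": 0.8, "kb2": 1.0}),
        "6": _law(net, "6", "connector", {"kc1": 1.0, "kc2": 1.0}),
    }
    return Model("fig8a", net, laws, "opposer live into balancer")


def _fig8b() -> Model:
    """Balancer module upstream (D = 1, balancer 2, connector 4) whose
    balancer's live regulation is opposed downstream by opposer 3."""
    net = Network.from_edges(
        [("1", "2", "activating"), ("2", "4", "activating"),
         ("1", "4", "inhibiting"), ("4", "6", "activating"),
         ("2", "5", "activating"), ("5", "6", "activating"),
         ("5", "3", "activating"), ("3", "5", "inhibiting")],
        "1", "6")
    g = {"kp": 1.0, "kd": 1.0}
    laws = {
        "1": _law(net, "1", "generic", dict(g)),
        "2": _law(net, "2", "balancer", {"kb1": 0.8, "kb2": 1.0}),
        "3": _law(net, "3", "opposer", {"ka": 1.0, "kb": 0.5}),
        "4": _law(net, "4", "connector", {"kc1": 0.5, "kc2": 1.0}),
        "5": _law(net, "5", "generic", dict(g)),
        "6": _law(net, "6", "generic", dict(g)),
    }
    return Model("fig8b", net, laws, "balancer live into opposer")


def _fig8c() -> Model:
    """Two opposer modules in series: opposer 3's live regulation is opposed
    downstream by opposer 5."""
    net = Network.from_edges(
        [("1", "2", "activating"), ("2", "3", "activating"),
         ("3", "2", "inhibiting"), ("3", "4", "activating"),
         ("4", "6", "activating"), ("2", "6", "activating"),
         ("4", "5", "activating"), ("5", "4", "inhibiting")],
        "1", "6")
    g = {"kp": 1.0, "kd": 1.0}
    laws = {
        "1": _law(net, "1", "generic", dict(g)),
        "2": _law(net, "2", "generic", dict(g)),
        "3": _law(net, "3", "opposer", {"ka": 1.0, "kb": 0.5}),
        "4": _law(net, "4", "generic", dict(g)),
        "5": _law(net, "5", "opposer", {"ka": 1.0, "kb": 0.5}),
        "6": _law(net, "6", "generic", dict(g)),
    }
    return Model("fig8c", net, laws, "opposer live into opposer")


def _fig8e() -> Model:
    """Non-trivial opposing set {3, 5} whose opposer 5 also feeds a route;
    that live route is balanced downstream (D = 6, balancer 7,
    connector 8)."""
    net = Network.from_edges(
        [("1", "2", "activating"), ("2", "8", "activating"),
         ("2", "5", "activating"), ("5", "2", "inhibiting"),
         ("4", "3", "activating"), ("3", "4", "inhibiting"),
         ("4", "5", "inhibiting"), ("5", "4", "activating"),
         ("5", "6", "activating"), ("6", "7", "activating"),
         ("7", "8", "activating"), ("6", "8", "inhibiting")],
        "1", "8")
    g = {"kp": 1.0, "kd": 1.0}
    laws = {
        "1": _law(net, "1", "generic", dict(g)),
        "2": _law(net, "2", "generic", dict(g)),
        "3": _law(net, "3", "opposer", {"ka": 1.0, "kb": 0.5}),
        "4": _law(net, "4", "generic", dict(g)),
        "5": _law(net, "5", "opposer", {"ka": 1.0, "kb": 1.0}),
        "6": _law(net, "6", "generic", dict(g)),
        "7": _law(net, "7", "balancer", {"kb1": 0.8, "kb2": 1.0}),
        "8": _law(net, "8", "connector", {"kc1": 1.0, "kc2": 1.0}),
    }
    return Model("fig8e", net, laws, "opposing set live into balancer")


def _fig8f() -> Model:
    """As fig8e but the live route from opposer 5 is opposed by a second
    opposer module (opposer 7) instead of balanced."""
    net = Network.from_edges(
        [("1", "2", "activating"), ("2", "8", "activating"),
         ("2", "5", "activating"), ("5", "2", "inhibiting"),
         ("4", "3", "activating"), ("3", "4", "inhibiting"),
         ("4", "5", "inhibiting"), ("5", "4", "activating"),
         ("5", "6", "activating"), ("6", "8", "activating"),
         ("6", "7", "activating"), ("7", "6", "inhibiting")],
        "1", "8")
    g = {"kp": 1.0, "kd": 1.0}
    laws = {
        "1": _law(net, "1", "generic", dict(g)),
        "2": _law(net, "2", "generic", dict(g)),
        "3": _law(net, "3", "opposer", {"ka": 1.0, "kb": 0.5}),
        "4": _law(net, "4", "generic", dict(g)),
        "5": _law(net, "5", "opposer", {"ka": 1.0, "kb": 1.0}),
        "6": _law(net, "6", "generic", dict(g)),
        "7": _law(net, "7", "opposer", {"ka": 1.0, "kb": 0.5}),
        "8": _law(net, "8", "generic", dict(g)),
    }
    return Model("fig8f", net, laws, "opposing set live into opposer")


_REGISTRY = {
    "fig2a": _fig2a,
    "fig2a_noloop": _fig2a_noloop,
    "fig2b": _fig2b,
    "fig2b_nonlinear": _fig2b_nonlinear,
    "antithetic": _antithetic,
    "fig3a": _fig3a,
    "fig3b": _fig3b,
    "fig3c": _fig3c,
    "fig6": _fig6,
    "fig7": _fig7_sol1,
    "fig7_sol1": _fig7_sol1,
    "fig7_sol2": _fig7_sol2,
    "fig8a": _fig8a,
    "fig8b": _fig8b,
    "fig8c": _fig8c,
    "fig8d": _fig3a,  # the 5-node non-trivial opposing set
    "fig8e": _fig8e,
    "fig8f": _fig8f,
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def paper_fixture(name: str) -> Model:
    """Return a registered fixture model by name."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {fixture_names()}") from None
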