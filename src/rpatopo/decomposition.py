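"""Decomposition of RPA-capable networks into Opposer and Balancer modules.

A network can exhibit robust perfect adaptation only if every route from
input to output is either *fully opposed* by an opposing set of nodes
(working inside feedback loops) or *balanced* by a diverter/balancer/
connector arrangement of parallel route segments.  This module detects both
kinds of basis module, applies the interconnection rules (mutually exclusive
kinetics roles, live/blind outgoing regulations, series coverage of live
regulations), and enumerates every valid decomposition.

Interpretive choices
--------------------
The formal statements behind opposing sets and balancer modules live in
material not reproduced here; the implemented conditions are reconstructed
from the narrative descriptions and worked examples and are documented in
``docs/methods.md``.  The load-bearing interpretations:

* An *opposing set* for a route is a connected collection of circuits
  disjoint from the route, with exactly one designated opposer per circuit
  (one node may serve adjacent circuits, as in chained opposing sets), whose
  master set (the union of those circuits) has exactly one external
  independent regulator, feeding a designated opposer; the collection must be
  embedded in some circuit contiguous with the route.  A mutual-annihilation
  pair -- a single 2-cycle whose two members are both designated -- is also
  accepted (the antithetic integral-feedback motif).
* A single opposer all of whose circuits are contiguous with the route is a
  trivial opposing set.
* A balancer module requires >= 2 route segments between diverter D and
  connector C (at least one internally disjoint pair), with D the sole
  independent regulator of the balancer set; any feedback loop lying inside
  balancers + {D, C} must lie wholly inside the balancer set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .network import (Circuit, Network, Route, circuit_route_relation,
                      dependents, enumerate_circuits, enumerate_routes,
                      independent_regulators)

__all__ = [
    "OpposingSet",
    "OpposerModule",
    "BalancerModule",
    "Decomposition",
    "opposer_candidates",
    "routes_fully_opposed_by",
    "routes_partially_opposed_by",
    "find_opposing_sets",
    "find_opposer_modules",
    "find_balancer_modules",
    "classify_outgoing_regulations",
    "enumerate_decompositions",
    "rpa_nodes",
]

MAX_INTERLINKED_CIRCUITS = 4


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpposingSet:
    """A collection of opposer nodes that can fully oppose route(s).

    ``master_set`` is the union of the interlinked route-disjoint circuits
    hosting the opposers (for a trivial single opposer it is just the opposer
    itself).  ``embedding_circuit`` is a circuit contiguous with the opposed
    route(s) through which the set is wired into the network.
    """

    opposers: frozenset
    master_set: frozenset
    opposed_routes: tuple
    embedding_circuit: Circuit

    def sort_key(self):
        return (tuple(sorted(self.master_set)), tuple(sorted(self.opposers)))


@dataclass(frozen=True)
class OpposerModule:
    """An opposing set together with its apex/base attachment to the route."""

    opposing_set: OpposingSet
    apex: str  # C: first route node receiving regulation back from the set
    base: str  # D: last route node regulating into the embedding circuit
    rpa_nodes: frozenset  # marked RPA within the module (regulators + masters)
    non_rpa_nodes: frozenset  # the opposers themselves

    @property
    def opposers(self) -> frozenset:
        return self.opposing_set.opposers

    @property
    def opposed_routes(self) -> tuple:
        return self.opposing_set.opposed_routes

    @property
    def kind(self) -> str:
        return "opposer"

    def role_nodes(self) -> frozenset:
        """Nodes holding an exclusive kinetics role (opposer kinetics)."""
        return self.opposing_set.opposers

    def active_nodes(self) -> frozenset:
        return self.opposing_set.master_set | set(
            self.opposing_set.embedding_circuit)

    def describe(self) -> dict:
        return {
            "kind": "opposer",
            "opposers": sorted(self.opposers),
            "master_set": sorted(self.opposing_set.master_set),
            "embedding_circuit": list(self.opposing_set.embedding_circuit),
            "apex": self.apex,
            "base": self.base,
            "opposed_routes": [list(r) for r in self.opposed_routes],
            "rpa_nodes": sorted(self.rpa_nodes),
            "non_rpa_nodes": sorted(self.non_rpa_nodes),
        }

    def sort_key(self):
        return ("opposer",) + self.opposing_set.sort_key()


@dataclass(frozen=True)
class BalancerModule:
    """Parallel route segments diverging at D and reconnecting at C."""

    diverter: str
    connector: str
    balancers: frozenset
    balanced_routes: tuple
    embedded_circuits: frozenset

    @property
    def kind(self) -> str:
        return "balancer"

    def role_nodes(self) -> frozenset:
        """Balancer + connector kinetics (the diverter keeps generic
        kinetics and is excluded)."""
        return self.balancers | {self.connector}

    def active_nodes(self) -> frozenset:
        return self.balancers | {self.diverter, self.connector}

    def describe(self) -> dict:
        return {
            "kind": "balancer",
            "diverter": self.diverter,
            "connector": self.connector,
            "balancers": sorted(self.balancers),
            "balanced_routes": [list(r) for r in self.balanced_routes],
            "embedded_circuits": [list(c) for c in
                                  sorted(self.embedded_circuits)],
        }

    def sort_key(self):
        return ("balancer", self.diverter, self.connector,
                tuple(sorted(self.balancers)))


@dataclass(frozen=True)
class Decomposition:
    """One valid partition of the route set among basis modules."""

    network: Network
    modules: tuple
    route_assignment: dict  # Route -> module index into self.modules
    regulation_classes: dict  # (source, target) -> "live" | "blind"
    series_links: tuple  # (upstream module index, ancillary module index)
    verdict: bool

    def describe(self) -> dict:
        return {
            "modules": [m.describe() for m in self.modules],
            "route_assignment": {"->".join(r): i for r, i in
                                 sorted(self.route_assignment.items())},
            "regulation_classes": {f"{u}->{v}": c for (u, v), c in
                                   sorted(self.regulation_classes.items())},
            "series_links": [list(l) for l in self.series_links],
            "rpa_nodes": sorted(rpa_nodes(self)),
            "verdict": self.verdict,
        }


# ---------------------------------------------------------------------------
# opposer side
# ---------------------------------------------------------------------------

def opposer_candidates(net: Network) -> list[str]:
    """Nodes that could carry opposer kinetics on their own.

    Requires participation in >= 1 feedback loop, exactly one independent
    regulator, and that regulator sharing a circuit with the node.  A node at
    the junction of two independent feedback loops necessarily has two
    regulators and is thereby excluded.
    """
    circuits = enumerate_circuits(net)
    out = []
    for node in net.nodes:
        own = [c for c in circuits if node in c]
        if not own:
            continue
        regs = independent_regulators(net, {node})
        if len(regs) != 1:
            continue
        if any(regs[0] in c for c in own):
            out.append(node)
    return out


def _split_opposed(net: Network, node: str) -> tuple[list, list]:
    circuits = [c for c in enumerate_circuits(net) if node in c]
    full, partial = [], []
    for r in enumerate_routes(net):
        if node in r:
            continue
        if all(circuit_route_relation(c, r) == "contiguous" for c in circuits):
            full.append(r)
        else:
            partial.append(r)
    return full, partial


def routes_fully_opposed_by(net: Network, node: str) -> list[Route]:
    """Routes disjoint from ``node`` whose every node-containing circuit is
    contiguous with the route (full opposition by a single opposer)."""
    if node not in opposer_candidates(net):
        raise ValueError(f"{node!r} is not an opposer candidate")
    return _split_opposed(net, node)[0]


def routes_partially_opposed_by(net: Network, node: str) -> list[Route]:
    """Routes disjoint from ``node`` that fail the contiguity condition:
    opposed only in part, and in need of a balancing mechanism."""
    if node not in opposer_candidates(net):
        raise ValueError(f"{node!r} is not an opposer candidate")
    return _split_opposed(net, node)[1]


def _fully_opposed_by_set(net: Network, opposers: frozenset,
                          master: frozenset, route: Route,
                          circuits: Sequence[Circuit]) -> bool:
    """A set fully opposes a route when the route avoids every opposer and
    each opposer's circuits are contiguous with the route or internal to the
    master set."""
    if set(route) & opposers:
        return False
    for o in opposers:
        for c in circuits:
            if o not in c:
                continue
            if circuit_route_relation(c, route) == "contiguous":
                continue
            if not set(c) <= master:
                return False
    return True


def _connected_collections(circs: Sequence[Circuit],
                           max_size: int) -> Iterator[tuple[Circuit, ...]]:
    """Sub-collections whose circuits chain together through shared nodes."""
    for size in range(1, min(max_size, len(circs)) + 1):
        for combo in itertools.combinations(circs, size):
            # connectivity of the circuit-overlap graph
            groups = [set(c) for c in combo]
            merged = groups[0]
            pending = groups[1:]
            progress = True
            while pending and progress:
                progress = False
                for g in list(pending):
                    if g & merged:
                        merged |= g
                        pending.remove(g)
                        progress = True
            if not pending:
                yield combo


def _designations(K: Sequence[Circuit]) -> Iterator[frozenset]:
    """Choices of designated opposers: one per circuit, a node may serve
    adjacent circuits; both members of a lone 2-cycle may be designated
    (mutual annihilation)."""
    options = []
    for c in K:
        opts = [frozenset({node}) for node in c]
        if len(c) == 2 and len(K) == 1:
            opts.append(frozenset(c))
        options.append(opts)
    seen = set()
    for pick in itertools.product(*options):
        O = frozenset().union(*pick)
        if O in seen:
            continue
        seen.add(O)
        ok = True
        for c in K:
            k = len(O & set(c))
            if k == 1:
                continue
            if k == 2 and len(c) == 2 and len(K) == 1:
                continue
            ok = False
            break
        if ok:
            yield O


def find_opposing_sets(net: Network, route: Route) -> list[OpposingSet]:
    """All minimal opposing sets able to fully oppose ``route``.

    Returns trivial (single-opposer) sets plus every interlinked-circuit
    collection satisfying the conditions in the module docstring.  Results
    are master-set minimal: a set is dropped when another valid set uses a
    strict subset of its master set.
    """
    circuits = enumerate_circuits(net)
    route_set = set(route)
    results: list[OpposingSet] = []

    # trivial single opposers: every circuit contiguous with the route
    for o in opposer_candidates(net):
        if o in route_set:
            continue
        own = [c for c in circuits if o in c]
        contiguous = [c for c in own
                      if circuit_route_relation(c, route) == "contiguous"]
        if own and len(contiguous) == len(own):
            reg = independent_regulators(net, {o})[0]
            withreg = [c for c in contiguous if reg in c]
            emb = (withreg or contiguous)[0]
            results.append(OpposingSet(frozenset({o}), frozenset({o}),
                                       (route,), emb))

    # interlinked collections of route-disjoint circuits
    disjoint = [c for c in circuits if not set(c) & route_set]
    for K in _connected_collections(disjoint, MAX_INTERLINKED_CIRCUITS):
        master = frozenset().union(*(frozenset(c) for c in K))
        ext = independent_regulators(net, master)
        if len(ext) != 1:
            continue
        fed = {r.target for r in net.regulations
               if r.source == ext[0] and r.target in master}
        embeddings = [c for c in circuits
                      if set(c) & route_set and set(c) & master]
        if not embeddings:
            continue
        for O in _designations(K):
            if not fed <= O:
                continue  # external regulation must feed designated opposers
            if any(not net.regulators_of(o) for o in O):
                continue
            if not _fully_opposed_by_set(net, O, master, route, circuits):
                continue
            results.append(OpposingSet(O, master, (route,), embeddings[0]))

    # master-set minimality
    masters = [s.master_set for s in results]
    keep = [s for s in results
            if not any(m < s.master_set for m in masters)]
    uniq: dict = {}
    for s in keep:
        uniq.setdefault((s.opposers, s.master_set), s)
    return sorted(uniq.values(), key=OpposingSet.sort_key)


def _assemble_module(net: Network, oset: OpposingSet,
                     routes: Sequence[Route],
                     circuits: Sequence[Circuit]) -> OpposerModule | None:
    opposed = tuple(r for r in routes
                    if _fully_opposed_by_set(net, oset.opposers,
                                             oset.master_set, r, circuits))
    if not opposed:
        return None
    oset = OpposingSet(oset.opposers, oset.master_set, opposed,
                       oset.embedding_circuit)
    emb = set(oset.embedding_circuit)
    route_hits = [n for r in opposed for n in r if n in emb]
    first = opposed[0]
    on_first = [n for n in first if n in emb]
    apex = on_first[0] if on_first else (route_hits[0] if route_hits
                                         else first[0])
    base = on_first[-1] if on_first else (route_hits[-1] if route_hits
                                          else first[-1])
    ext = independent_regulators(net, oset.master_set)
    marked = set(oset.master_set - oset.opposers)
    marked.update(ext)
    marked.update(route_hits)
    return OpposerModule(oset, apex, base, frozenset(marked), oset.opposers)


def find_opposer_modules(net: Network) -> list[OpposerModule]:
    """Opposer modules: opposing sets with their full opposed-route lists."""
    routes = enumerate_routes(net)
    circuits = enumerate_circuits(net)
    by_key: dict = {}
    for r in routes:
        for s in find_opposing_sets(net, r):
            by_key.setdefault((s.opposers, s.master_set), s)
    modules = []
    for key in sorted(by_key, key=lambda k: (tuple(sorted(k[1])),
                                             tuple(sorted(k[0])))):
        mod = _assemble_module(net, by_key[key], routes, circuits)
        if mod is not None:
            modules.append(mod)
    return modules


# ---------------------------------------------------------------------------
# balancer side
# ---------------------------------------------------------------------------

def find_balancer_modules(net: Network) -> list[BalancerModule]:
    """All diverter/connector pairs implementing the balancing mechanism.

    Empty whenever input == output: balancing needs >= 2 distinct routes, and
    a single input/output node admits only the single-node route.
    """
    if net.input == net.output:
        return []
    routes = enumerate_routes(net)
    circuits = enumerate_circuits(net)
    route_nodes = set().union(*(set(r) for r in routes))
    modules = []
    for D in net.nodes:
        for C in net.nodes:
            if D == C:
                continue
            segs = set()
            for r in routes:
                if D in r and C in r and r.index(D) < r.index(C):
                    segs.add(r[r.index(D):r.index(C) + 1])
            if len(segs) < 2:
                continue
            interiors = [set(s[1:-1]) for s in segs]
            if not any(not a & b
                       for a, b in itertools.combinations(interiors, 2)):
                continue  # need an internally node-disjoint pair
            B: set = set().union(*interiors)
            if not B:
                continue
            # absorb feedback loops hanging fully off the balancer segments
            changed = True
            while changed:
                changed = False
                for c in circuits:
                    cs = set(c)
                    if cs & B and not cs <= B:
                        if not (cs - B) & (route_nodes | {D, C}):
                            B |= cs
                            changed = True
            if D in B or C in B:
                continue
            if independent_regulators(net, B) != [D]:
                continue
            # any loop confined to balancers+{D,C} must be fully embedded
            if any(set(c) <= B | {D, C} and not set(c) <= B
                   for c in circuits):
                continue
            balanced = tuple(
                r for r in routes
                if D in r and C in r and r.index(D) < r.index(C)
                and set(r[r.index(D) + 1:r.index(C)]) <= B)
            if len(balanced) < 2:
                continue
            embedded = frozenset(c for c in circuits if set(c) <= B)
            modules.append(BalancerModule(D, C, frozenset(B), balanced,
                                          embedded))
    return sorted(modules, key=BalancerModule.sort_key)


# ---------------------------------------------------------------------------
# interconnection rules
# ---------------------------------------------------------------------------

def classify_outgoing_regulations(net: Network, module) -> dict:
    """Label extramodular regulations live (from non-RPA nodes) or blind
    (from RPA nodes)."""
    active = module.active_nodes()
    if module.kind == "opposer":
        opp = set(module.opposers)
        live_src = opp | dependents(net, opp)
        blind_seed = set(module.rpa_nodes)
        blind_src = blind_seed | dependents(net, blind_seed, exclude=opp)
    else:
        live_src = set(module.balancers) | {module.diverter}
        blind_seed = {module.connector}
        blind_src = blind_seed | dependents(net, blind_seed,
                                            exclude=set(module.balancers))
    out = {}
    for reg in net.regulations:
        if reg.target in active:
            continue
        if reg.source in live_src:
            out[(reg.source, reg.target)] = "live"
        elif reg.source in blind_src:
            out[(reg.source, reg.target)] = "blind"
    return out


def rpa_nodes(d: Decomposition) -> set:
    """Nodes guaranteed the RPA property by a decomposition.

    Union of each module's marked nodes, closed under dependents reached only
    through RPA nodes; opposers, balancers, and diverters can never join (they
    absorb the input dependence)."""
    net = d.network
    marked: set = set()
    barred: set = set()
    for m in d.modules:
        if m.kind == "opposer":
            marked |= set(m.rpa_nodes)
            barred |= set(m.opposers)
        else:
            marked.add(m.connector)
            barred |= set(m.balancers) | {m.diverter}
    marked -= barred
    if not marked:
        return set()
    return marked | dependents(net, marked, exclude=barred)


def _canonical_assignment(routes, chosen) -> dict | None:
    """Balancer modules absorb their routes automatically; remaining routes
    go to the first covering opposer module.  None when some route is
    uncovered or two balancer modules claim the same route."""
    assignment: dict = {}
    for r in routes:
        bal = [i for i, m in enumerate(chosen)
               if m.kind == "balancer" and r in m.balanced_routes]
        if len(bal) > 1:
            return None
        if bal:
            assignment[r] = bal[0]
            continue
        opp = [i for i, m in enumerate(chosen)
               if m.kind == "opposer" and r in m.opposed_routes]
        if not opp:
            return None
        assignment[r] = opp[0]
    return assignment


def enumerate_decompositions(net: Network) -> list[Decomposition]:
    """Every valid decomposition of the route set into basis modules.

    A subset of candidate modules is valid when the canonical assignment
    covers all routes, every module is used, kinetics roles are mutually
    exclusive across modules, and the output node ends up with the RPA
    property.  An empty result means the topology cannot support RPA.
    """
    routes = enumerate_routes(net)
    candidates = find_balancer_modules(net) + find_opposer_modules(net)
    if len(candidates) > 16:
        raise ValueError(
            f"{len(candidates)} candidate modules: decomposition search "
            "would be intractable; analyze a pruned or smaller network")
    out = []
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(range(len(candidates)), size):
            chosen = [candidates[i] for i in combo]
            roles = [m.role_nodes() for m in chosen]
            union: set = set()
            clash = False
            for rset in roles:
                if rset & union:
                    clash = True
                    break
                union |= rset
            if clash:
                continue
            assignment = _canonical_assignment(routes, chosen)
            if assignment is None:
                continue
            if set(assignment.values()) != set(range(len(chosen))):
                continue  # idle module: same partition exists without it
            reg_classes: dict = {}
            for m in chosen:
                reg_classes.update(classify_outgoing_regulations(net, m))
            links = set()
            for i, m in enumerate(chosen):
                for (u, v), cls in classify_outgoing_regulations(net,
                                                                 m).items():
                    if cls != "live":
                        continue
                    for r in routes:
                        if u in r and v in r and r.index(v) == r.index(u) + 1:
                            j = assignment[r]
                            if j != i:
                                links.add((i, j))
            d = Decomposition(net, tuple(chosen), assignment, reg_classes,
                              tuple(sorted(links)), True)
            if net.output in rpa_nodes(d):
                out.append(d)
    return out
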