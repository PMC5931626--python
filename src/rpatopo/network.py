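"""Directed signaling networks and the graph predicates used by RPA analysis.

A :class:`Network` is a directed graph of signed regulations together with a
designated input node (the recipient of the exogenous stimulus *I*) and a
designated output node (the read-out whose steady state is tested for
adaptation).  Input and output may coincide.

The analysis downstream of this module is built entirely from three kinds of
structure:

* **routes** -- simple directed paths from input to output,
* **circuits** -- simple directed cycles (feedback loops) of length >= 2, and
* **kinetic multipliers** -- implicit single-node cycles (the diagonal
  Jacobian entries), which are never stored as explicit edges.

Edge signs are carried through for the simulation layer; all topological
predicates here ignore them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Literal, NamedTuple, Sequence

import networkx as nx

__all__ = [
    "Sign",
    "Regulation",
    "Network",
    "NetworkError",
    "NoRouteError",
    "PruneResult",
    "validate_and_prune",
    "enumerate_routes",
    "enumerate_circuits",
    "circuit_route_relation",
    "independent_regulators",
    "dependents",
    "canonical_circuit",
]

Sign = Literal["activating", "inhibiting", "unspecified"]
SIGNS: tuple[str, ...] = ("activating", "inhibiting", "unspecified")

#: A route is an ordered node sequence from input to output (no repeats).
Route = tuple[str, ...]
#: A circuit is a node cycle stored in canonical rotation (see
#: :func:`canonical_circuit`); consecutive pairs, cyclically, are regulations.
Circuit = tuple[str, ...]


class NetworkError(ValueError):
    """Structural problem with a network definition."""


class NoRouteError(NetworkError):
    """The output node is unreachable from the input node."""


@dataclass(frozen=True, order=True)
class Regulation:
    """A signed directed regulation ``source -> target``.

    Self-regulation is never represented as an edge: the diagonal Jacobian
    entry (kinetic multiplier) exists implicitly for every node.
    """

    source: str
    target: str
    sign: str = "unspecified"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise NetworkError(
                f"self-regulation {self.source}->{self.target} is implicit "
                "(kinetic multiplier), not an explicit edge"
            )
        if self.sign not in SIGNS:
            raise NetworkError(f"unknown sign {self.sign!r} for "
                               f"{self.source}->{self.target}")


@dataclass(frozen=True)
class Network:
    """A directed signaling network with designated input and output nodes."""

    nodes: tuple[str, ...]
    regulations: tuple[Regulation, ...]
    input: str
    output: str

    def __post_init__(self) -> None:
        nodes = tuple(sorted(self.nodes))
        object.__setattr__(self, "nodes", nodes)
        if len(set(nodes)) != len(nodes):
            dupes = sorted({n for n in nodes if list(nodes).count(n) > 1})
            raise NetworkError(f"duplicate node ids: {dupes}")
        node_set = set(nodes)
        seen: set[tuple[str, str]] = set()
        for reg in self.regulations:
            for end in (reg.source, reg.target):
                if end not in node_set:
                    raise NetworkError(
                        f"regulation {reg.source}->{reg.target} references "
                        f"undeclared node {end!r}")
            pair = (reg.source, reg.target)
            if pair in seen:
                raise NetworkError(f"duplicate regulation {pair[0]}->{pair[1]}")
            seen.add(pair)
        object.__setattr__(
            self, "regulations",
            tuple(sorted(self.regulations, key=lambda r: (r.source, r.target))))
        for role, node in (("input", self.input), ("output", self.output)):
            if node not in node_set:
                raise NetworkError(f"{role} node {node!r} not in node set")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str] | tuple[str, str, str]],
                   input: str, output: str,
                   nodes: Iterable[str] | None = None) -> "Network":
        """Build a network from ``(source, target[, sign])`` tuples."""
        regs = []
        for edge in edges:
            if len(edge) == 2:
                regs.append(Regulation(edge[0], edge[1]))
            else:
                regs.append(Regulation(edge[0], edge[1], edge[2]))
        node_set = {input, output}
        for reg in regs:
            node_set.update((reg.source, reg.target))
        if nodes is not None:
            node_set.update(nodes)
        return cls(tuple(sorted(node_set)), tuple(regs), input, output)

    # -- views ---------------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.nodes)

    def graph(self) -> nx.DiGraph:
        """The underlying :class:`networkx.DiGraph` (signs as edge data)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for reg in self.regulations:
            g.add_edge(reg.source, reg.target, sign=reg.sign)
        return g

    def has_edge(self, source: str, target: str) -> bool:
        return any(r.source == source and r.target == target
                   for r in self.regulations)

    def regulators_of(self, node: str) -> list[str]:
        return sorted(r.source for r in self.regulations if r.target == node)

    def targets_of(self, node: str) -> list[str]:
        return sorted(r.target for r in self.regulations if r.source == node)

    def sign_of(self, source: str, target: str) -> str:
        for r in self.regulations:
            if r.source == source and r.target == target:
                return r.sign
        raise KeyError(f"no regulation {source}->{target}")

    def subnetwork(self, keep: Iterable[str]) -> "Network":
        keep_set = set(keep)
        if self.input not in keep_set or self.output not in keep_set:
            raise NetworkError("subnetwork must retain input and output nodes")
        regs = tuple(r for r in self.regulations
                     if r.source in keep_set and r.target in keep_set)
        return Network(tuple(sorted(keep_set)), regs, self.input, self.output)


class PruneResult(NamedTuple):
    network: Network
    removed: tuple[str, ...]


def canonical_circuit(cycle: Sequence[str]) -> Circuit:
    """Rotate a cycle so it starts at its lexicographically smallest node."""
    cycle = tuple(cycle)
    k = cycle.index(min(cycle))
    return cycle[k:] + cycle[:k]


def enumerate_routes(net: Network) -> list[Route]:
    """All simple directed paths input -> output, in lexicographic order.

    When input and output coincide the single-node route ``(input,)`` is the
    only route: the stimulus enters and is read out at the same node.
    """
    if net.input == net.output:
        return [(net.input,)]
    g = net.graph()
    paths = [tuple(p) for p in nx.all_simple_paths(g, net.input, net.output)]
    return sorted(paths)


def enumerate_circuits(net: Network) -> list[Circuit]:
    """All simple directed cycles of length >= 2, canonical rotation.

    Deterministic order: by length, then lexicographically.
    """
    g = net.graph()
    cycles = [canonical_circuit(c) for c in nx.simple_cycles(g) if len(c) >= 2]
    return sorted(set(cycles), key=lambda c: (len(c), c))


def circuit_route_relation(c: Circuit, r: Route) -> str:
    """``"contiguous"`` if circuit and route share >= 1 node, else
    ``"disjoint"``."""
    return "contiguous" if set(c) & set(r) else "disjoint"


def independent_regulators(net: Network, S: Iterable[str]) -> list[str]:
    """Nodes outside ``S`` that regulate at least one member of ``S``.

    The exogenous stimulus *I* is not a node and is never counted.
    """
    s = set(S)
    if not s:
        raise ValueError("S must be nonempty")
    unknown = s - set(net.nodes)
    if unknown:
        raise NetworkError(f"unknown node ids in S: {sorted(unknown)}")
    return sorted({r.source for r in net.regulations
                   if r.target in s and r.source not in s})


def dependents(net: Network, S: Iterable[str],
               exclude: Iterable[str] = ()) -> set[str]:
    """Least fixed point of nodes whose every regulator traces back to ``S``.

    A node ``u`` outside ``S`` is a dependent if it has at least one regulator
    and all of its regulators lie in ``S`` or in the current dependent set.
    Nodes listed in ``exclude`` can never become dependents (used to bar
    opposer nodes, which never inherit the RPA property).
    """
    s = set(S)
    if not s:
        raise ValueError("S must be nonempty")
    excluded = set(exclude)
    deps: set[str] = set()
    changed = True
    while changed:
        changed = False
        closure = s | deps
        for u in net.nodes:
            if u in closure or u in excluded:
                continue
            regs = net.regulators_of(u)
            if regs and all(v in closure for v in regs):
                deps.add(u)
                changed = True
    return deps


def validate_and_prune(net: Network) -> PruneResult:
    """Restrict a network to its connected-and-transmissive core.

    Keeps every node that lies on a route, then repeatedly adds whole circuits
    that share at least one node with the kept set (circuits contiguous with a
    route, or chained to one through other kept circuits).  Anything else can
    play no role in the input--output minor's route/circuit structure and is
    removed.  Idempotent.

    Raises :class:`NoRouteError` when the output is unreachable from the input
    (and the two are distinct).
    """
    if net.input != net.output:
        g = net.graph()
        if not nx.has_path(g, net.input, net.output):
            raise NoRouteError(
                f"output {net.output!r} unreachable from input {net.input!r}")
    routes = enumerate_routes(net)
    keep: set[str] = set()
    for r in routes:
        keep.update(r)
    circuits = enumerate_circuits(net)
    changed = True
    while changed:
        changed = False
        for c in circuits:
            cs = set(c)
            if cs & keep and not cs <= keep:
                keep |= cs
                changed = True
    removed = tuple(sorted(set(net.nodes) - keep))
    return PruneResult(net.subnetwork(keep), removed)


# -- brute-force oracles (test support, deliberately naive) -------------------

def brute_force_routes(net: Network) -> list[Route]:
    """Depth-first path enumeration, independent of networkx."""
    if net.input == net.output:
        return [(net.input,)]
    succ = {u: net.targets_of(u) for u in net.nodes}
    out: list[Route] = []

    def walk(path: list[str]) -> None:
        tip = path[-1]
        if tip == net.output:
            out.append(tuple(path))
            return
        for v in succ[tip]:
            if v not in path:
                walk(path + [v])

    walk([net.input])
    return sorted(out)


def brute_force_circuits(net: Network) -> list[Circuit]:
    """Cycle enumeration by rooted depth-first search from each minimum node."""
    succ = {u: net.targets_of(u) for u in net.nodes}
    found: set[Circuit] = set()

    def walk(root: str, path: list[str]) -> None:
        tip = path[-1]
        for v in succ[tip]:
            if v == root and len(path) >= 2:
                found.add(canonical_circuit(path))
            elif v > root and v not in path:
                walk(root, path + [v])

    for root in net.nodes:
        walk(root, [root])
    return sorted(found, key=lambda c: (len(c), c))
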