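"""Symbolic Jacobian, input--output minor, and the RPA-equation term set **R**.

For an ``n``-node network with rates ``f_1..f_n``, the Jacobian entry
``J[i, k] = d f_i / d P_k`` is structurally nonzero exactly when the network
contains the regulation ``k -> i`` or when ``i == k`` (the implicit kinetic
multiplier).  Robust perfect adaptation requires the input--output minor
``M_IO`` (Jacobian with the input *row* and output *column* removed) to have
zero determinant for all inputs, while the full Jacobian stays nonsingular.

The permutation expansion of ``det(M_IO)`` decomposes combinatorially: every
surviving term is the product of

* one *route factor* (a simple path input -> output),
* zero or more *circuit products* (vertex-disjoint simple cycles), and
* *kinetic multipliers* (diagonal entries) on every remaining node,

with a sign given by the parity of the underlying row/column bijection.  This
module enumerates those terms directly from the graph and cross-checks against
a brute-force symbolic determinant.

Symbols are named ``j_<target>_<source>`` for ``d f_target / d P_source``
(note the target-first orientation; ``j_B_D`` is the response of node B's rate
to node D's activity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import sympy

from .network import (Circuit, Network, Route, canonical_circuit,
                      enumerate_routes)

__all__ = [
    "SymbolicJacobian",
    "MinorMatrix",
    "RPATerm",
    "RPAEquation",
    "SizeCapError",
    "symbolic_jacobian",
    "input_output_minor",
    "expand_rpa_equation",
    "brute_force_minor_determinant",
    "max_term_count",
    "group_terms_by_route",
]

DEFAULT_NODE_CAP = 12


class SizeCapError(ValueError):
    """Expansion refused: the network exceeds the configured node cap."""

    def __init__(self, n: int, cap: int):
        self.n = n
        self.cap = cap
        self.tau_bound = max_term_count(n) if n >= 2 else 0
        super().__init__(
            f"network has {n} nodes (cap {cap}); the RPA equation could hold "
            f"up to {self.tau_bound} terms -- raise max_nodes to force")


def jac_symbol(target: str, source: str) -> sympy.Symbol:
    """Symbol for the Jacobian entry ``d f_target / d P_source``."""
    return sympy.Symbol(f"j_{target}_{source}")


@dataclass(frozen=True)
class SymbolicJacobian:
    """Structural Jacobian: one free symbol per possible nonzero entry."""

    nodes: tuple[str, ...]
    entries: dict  # (target, source) -> sympy.Symbol

    @property
    def order(self) -> int:
        return len(self.nodes)

    def entry(self, target: str, source: str) -> sympy.Expr:
        return self.entries.get((target, source), sympy.Integer(0))

    def matrix(self) -> sympy.Matrix:
        return sympy.Matrix(
            [[self.entry(i, k) for k in self.nodes] for i in self.nodes])


@dataclass(frozen=True)
class MinorMatrix:
    """Labeled (n-1) x (n-1) input--output minor of the Jacobian.

    Rows are indexed by all nodes except the input; columns by all nodes
    except the output.  When input == output this is the principal minor
    deleting that node's row and column.
    """

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    matrix: sympy.Matrix

    def entry(self, target: str, source: str) -> sympy.Expr:
        return self.matrix[self.rows.index(target), self.cols.index(source)]

    def det(self) -> sympy.Expr:
        if not self.rows:
            return sympy.Integer(1)  # empty minor: 0x0 determinant
        return sympy.expand(self.matrix.det(method="berkowitz"))


@dataclass(frozen=True)
class RPATerm:
    """One signed term of the RPA equation's determinant expansion.

    ``route``, the nodes of ``circuits`` and ``multipliers`` partition the
    node set of the network.
    """

    sign: int
    route: Route
    circuits: frozenset  # of Circuit tuples
    multipliers: frozenset  # of node ids

    def nodes_covered(self) -> set[str]:
        cov = set(self.route) | set(self.multipliers)
        for c in self.circuits:
            cov |= set(c)
        return cov

    def expression(self) -> sympy.Expr:
        """Symbolic product equal to this term's contribution to det(M_IO)."""
        expr = sympy.Integer(self.sign)
        for u, v in zip(self.route, self.route[1:]):
            expr *= jac_symbol(v, u)
        for circ in sorted(self.circuits):
            ring = list(circ) + [circ[0]]
            for u, v in zip(ring, ring[1:]):
                expr *= jac_symbol(v, u)
        for m in sorted(self.multipliers):
            expr *= jac_symbol(m, m)
        return expr

    def sort_key(self):
        return (self.route, tuple(sorted(self.circuits)),
                tuple(sorted(self.multipliers)))


@dataclass(frozen=True)
class RPAEquation:
    """The full term set **R** for one network."""

    network: Network
    terms: tuple[RPATerm, ...]

    @property
    def term_count(self) -> int:
        """tau, the number of terms; tau <= (n-1)!."""
        return len(self.terms)

    def expression(self) -> sympy.Expr:
        return sympy.expand(sympy.Add(*[t.expression() for t in self.terms]))

    def summary(self) -> dict:
        from .network import enumerate_circuits
        return {
            "n": self.network.n,
            "tau": self.term_count,
            "tau_bound": max_term_count(self.network.n)
            if self.network.n >= 2 else 0,
            "route_count": len(enumerate_routes(self.network)),
            "circuit_count": len(enumerate_circuits(self.network)),
        }


def max_term_count(n: int) -> int:
    """Maximal number of RPA-equation terms for a fully connected n-node
    network: (n-1)!."""
    if n < 2:
        raise ValueError("term-count bound requires n >= 2")
    return math.factorial(n - 1)


def symbolic_jacobian(net: Network) -> SymbolicJacobian:
    """One free symbol per structural nonzero of the Jacobian."""
    entries = {}
    for node in net.nodes:
        entries[(node, node)] = jac_symbol(node, node)
    for reg in net.regulations:
        entries[(reg.target, reg.source)] = jac_symbol(reg.target, reg.source)
    return SymbolicJacobian(net.nodes, entries)


def input_output_minor(J: SymbolicJacobian, input: str,
                       output: str) -> MinorMatrix:
    """Delete the input row and the output column from the Jacobian."""
    for node in (input, output):
        if node not in J.nodes:
            raise KeyError(f"unknown node id {node!r}")
    rows = tuple(n for n in J.nodes if n != input)
    cols = tuple(n for n in J.nodes if n != output)
    mat = sympy.Matrix([[J.entry(r, c) for c in cols] for r in rows])
    return MinorMatrix(rows, cols, mat)


def _permutation_sign(rows: Sequence[str], cols: Sequence[str],
                      assignment: dict) -> int:
    """Sign of the row->column bijection ``assignment`` in det ordering."""
    col_index = {c: i for i, c in enumerate(cols)}
    perm = [col_index[assignment[r]] for r in rows]
    sign = 1
    seen = [False] * len(perm)
    for start in range(len(perm)):
        if seen[start]:
            continue
        length = 0
        k = start
        while not seen[k]:
            seen[k] = True
            k = perm[k]
            length += 1
        if length % 2 == 0:
            sign = -sign
    return sign


def _cycle_partitions(succ: dict, remaining: tuple[str, ...]
                      ) -> Iterator[tuple[tuple[Circuit, ...],
                                          tuple[str, ...]]]:
    """Partitions of ``remaining`` into vertex-disjoint simple cycles (length
    >= 2, following edges in ``succ``) plus singleton kinetic multipliers."""
    if not remaining:
        yield (), ()
        return
    v = remaining[0]
    rest = remaining[1:]
    # v as a kinetic multiplier (single-node cycle; always structurally valid)
    for cycles, mults in _cycle_partitions(succ, rest):
        yield cycles, (v,) + mults
    # v inside a multi-node cycle drawn from the remaining nodes
    allowed = set(remaining)

    def extend(path: list[str]) -> Iterator[tuple[str, ...]]:
        tip = path[-1]
        for w in succ.get(tip, ()):
            if w == v and len(path) >= 2:
                yield tuple(path)
            elif w in allowed and w not in path and w > v:
                yield from extend(path + [w])

    for cyc in extend([v]):
        left = tuple(u for u in rest if u not in cyc)
        for cycles, mults in _cycle_partitions(succ, left):
            yield (canonical_circuit(cyc),) + cycles, mults


def expand_rpa_equation(net: Network,
                        max_nodes: int = DEFAULT_NODE_CAP) -> RPAEquation:
    """Enumerate the full term set **R** of det(M_IO).

    Every term pairs a route with a vertex-disjoint cycle/multiplier cover of
    the remaining nodes; the sign comes from the parity of the corresponding
    permutation of the minor.  Terms are returned in a deterministic order.
    """
    n = net.n
    if n > max_nodes:
        raise SizeCapError(n, max_nodes)
    succ = {u: sorted(net.targets_of(u)) for u in net.nodes}
    rows = tuple(u for u in net.nodes if u != net.input)
    cols = tuple(u for u in net.nodes if u != net.output)
    terms: list[RPATerm] = []
    for route in enumerate_routes(net):
        remaining = tuple(u for u in net.nodes if u not in route)
        for circuits, multipliers in _cycle_partitions(succ, remaining):
            assignment = {}  # row (target) -> column (source)
            for u, v in zip(route, route[1:]):
                assignment[v] = u
            for circ in circuits:
                ring = list(circ) + [circ[0]]
                for u, v in zip(ring, ring[1:]):
                    assignment[v] = u
            for m in multipliers:
                assignment[m] = m
            sign = _permutation_sign(rows, cols, assignment)
            terms.append(RPATerm(sign, route, frozenset(circuits),
                                 frozenset(multipliers)))
    terms.sort(key=RPATerm.sort_key)
    return RPAEquation(net, tuple(terms))


def brute_force_minor_determinant(net: Network, max_nodes: int = 8
                                  ) -> sympy.Expr:
    """Cofactor-expansion determinant of the minor (independent oracle)."""
    if net.n > max_nodes:
        raise SizeCapError(net.n, max_nodes)
    J = symbolic_jacobian(net)
    return input_output_minor(J, net.input, net.output).det()


def group_terms_by_route(eq: RPAEquation) -> dict:
    """Partition **R** by route factor (deterministic group order)."""
    groups: dict[Route, list[RPATerm]] = {}
    for term in eq.terms:
        groups.setdefault(term.route, []).append(term)
    return {route: groups[route] for route in sorted(groups)}
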