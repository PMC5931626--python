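"""Exhaustive screening of small topologies with coincident input/output.

When one node receives the stimulus and is also the read-out, balancing is
impossible (it needs at least two distinct routes), so adaptation must come
from opposition.  This module enumerates every connected-and-transmissive
topology on up to ``n_max`` nodes with input == output (up to relabeling of
the non-input nodes), screens each numerically for RPA with canonical
kinetics under random parameter draws, and lets callers cross-check the
screen against the structural opposer detection.

The numeric screen is detector-independent: it tries the all-generic
assignment plus opposer kinetics at each structurally eligible node (one
regulator -- a kinetics-class requirement, not a topological search), and
reports the first configuration whose steady states adapt.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np

from .kinetics import (ODESystem, find_steady_state, make_rate_law)
from .network import Network, NetworkError, validate_and_prune

__all__ = ["coincident_topologies", "screen_rpa", "ScreenResult"]


def _canonical_key(n: int, edges: frozenset) -> tuple:
    """Isomorphism key with the input node P0 held fixed."""
    others = [f"P{i}" for i in range(1, n)]
    best = None
    for perm in itertools.permutations(others):
        relabel = {"P0": "P0"}
        relabel.update(dict(zip(others, perm)))
        key = tuple(sorted((relabel[u], relabel[v]) for u, v in edges))
        if best is None or key < best:
            best = key
    return best


def coincident_topologies(n_max: int = 4):
    """Yield every pruned-canonical topology with input == output == P0 on
    1..n_max nodes, one representative per isomorphism class (P0 fixed)."""
    seen = set()
    for n in range(1, n_max + 1):
        nodes = [f"P{i}" for i in range(n)]
        pairs = [(u, v) for u in nodes for v in nodes if u != v]
        for bits in range(2 ** len(pairs)):
            edges = frozenset(p for i, p in enumerate(pairs)
                              if bits >> i & 1)
            try:
                net = Network.from_edges(edges, "P0", "P0", nodes=nodes)
                pruned, removed = validate_and_prune(net)
            except NetworkError:
                continue
            if removed:
                continue  # equivalent to a smaller topology
            key = (n, _canonical_key(n, edges))
            if key in seen:
                continue
            seen.add(key)
            yield pruned


@dataclass
class ScreenResult:
    network: Network
    passed: bool
    opposer_assignment: str | None  # node given opposer kinetics, or None
    n_configs: int


def _canonical_laws(net: Network, opposer_at: str | None,
                    orders: dict | None = None):
    """Canonical kinetics; ``orders`` maps (node, regulator) to a power-law
    interaction order for generic nodes.

    Randomizing the orders keeps the screen honest: with every interaction
    exactly first-order, circuit products can cancel kinetic-multiplier
    products identically (a degeneracy of that one rate-law family), which
    would score topologies as adapting without any integral-control
    structure.  Genuine opposer-driven adaptation survives arbitrary orders.
    """
    laws = {}
    for node in net.nodes:
        regs = [(s, "unspecified") for s in net.regulators_of(node)]
        if node == opposer_at:
            laws[node] = make_rate_law(node, "opposer", regs,
                                       {"ka": 1.0, "kb": 0.5},
                                       stimulus=(node == net.input))
        else:
            law = make_rate_law(node, "generic", regs,
                                {"kp": 1.0, "kd": 1.0},
                                stimulus=(node == net.input))
            if orders:
                exps = tuple((s, orders[(node, s)]) for s, _ in regs
                             if (node, s) in orders)
                if exps:
                    law = replace(law, form="power", exponents=exps)
            laws[node] = law
    return laws


def screen_rpa(net: Network, n_draws: int = 20, seed: int = 0,
               levels: tuple = (0.2, 0.6, 1.0),
               tol: float = 1e-6) -> ScreenResult:
    """Numeric RPA screen with canonical kinetics.

    Configurations: all-generic, then opposer kinetics at each node with a
    single regulator.  Each configuration gets ``n_draws`` log-uniform
    parameter draws (factors in [0.1, 10]); a configuration passes when all
    input levels reach a positive steady state with nonsingular Jacobian and
    the output varies by at most ``tol`` (relative).  Steady states are
    located algebraically (``direct`` mode) for throughput.
    """
    eligible = [None] + [v for v in net.nodes
                         if len(net.regulators_of(v)) == 1]
    out_node = net.output
    pairs = [(r.target, r.source) for r in net.regulations]
    for ci, opposer_at in enumerate(eligible):
        base = ODESystem(net, _canonical_laws(net, opposer_at))
        index = base.param_index()
        rng = np.random.default_rng(seed * 1009 + ci)
        for _ in range(n_draws):
            draws = np.exp(rng.uniform(np.log(0.1), np.log(10.0),
                                       size=len(index)))
            factors: dict = {}
            for (node, key), val in zip(index, draws):
                factors.setdefault(node, {})[key] = float(val)
            orders = {p: float(o) for p, o in
                      zip(pairs, np.exp(rng.uniform(np.log(0.5), np.log(2.0),
                                                    size=len(pairs))))}
            trial = ODESystem(
                net, _canonical_laws(net, opposer_at, orders)).scaled(factors)
            vals = []
            ok = True
            x0 = np.ones(len(trial.order))
            for level in levels:
                ss = find_steady_state(trial, level, x0, method="direct")
                if not (ss.converged and ss.jacobian_nonsingular
                        and min(ss.values.values()) > 1e-8):
                    # the floor rejects the all-off root a direct solve can
                    # land on (every species extinct is always a fixed point
                    # of mass-action production driven by its regulators)
                    ok = False
                    break
                x0 = np.array([ss.values[n] for n in trial.order])
                vals.append(ss.values[out_node])
            if not ok:
                continue
            ref = vals[0]
            if ref > 0 and max(abs(v - ref) for v in vals) / ref <= tol:
                return ScreenResult(net, True, opposer_at, len(eligible))
    return ScreenResult(net, False, None, len(eligible))
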