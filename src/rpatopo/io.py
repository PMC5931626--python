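"""Reading and writing networks, models, term sets, and reports.

The package's native format is a small JSON schema::

    {"nodes": ["X", "O"],
     "edges": [{"source": "X", "target": "O", "sign": "activating"},
               {"source": "O", "target": "X", "sign": "inhibiting"}],
     "input": "X", "output": "X"}

Model files extend it with per-node kinetics and rate parameters.  Writing
is canonical (sorted nodes and edges, fixed key order, two-space indent) so
write -> read -> write round-trips byte-stably.  Validation is performed
in-package with JSON-pointer style error locations.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .kinetics import RateLaw
from .network import Network, Regulation, SIGNS
from .rpa_equation import RPAEquation

__all__ = [
    "SchemaError",
    "read_network", "write_network", "network_to_obj", "network_from_obj",
    "read_model", "write_model",
    "export_graphml", "write_terms",
]


class SchemaError(ValueError):
    """Input file violates the network/model schema."""

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


def _require(obj: dict, key: str, typ, pointer: str):
    if key not in obj:
        raise SchemaError(f"{pointer}/{key}", "missing required key")
    if not isinstance(obj[key], typ):
        raise SchemaError(f"{pointer}/{key}",
                          f"expected {typ.__name__}, got "
                          f"{type(obj[key]).__name__}")
    return obj[key]


def network_from_obj(obj: dict, pointer: str = "") -> Network:
    if not isinstance(obj, dict):
        raise SchemaError(pointer or "/", "expected a JSON object")
    nodes = _require(obj, "nodes", list, pointer)
    for i, n in enumerate(nodes):
        if not isinstance(n, str) or not n:
            raise SchemaError(f"{pointer}/nodes/{i}",
                              "node ids must be nonempty strings")
    edges = _require(obj, "edges", list, pointer)
    regs = []
    node_set = set(nodes)
    for i, e in enumerate(edges):
        ep = f"{pointer}/edges/{i}"
        if not isinstance(e, dict):
            raise SchemaError(ep, "expected an edge object")
        src = _require(e, "source", str, ep)
        tgt = _require(e, "target", str, ep)
        sign = e.get("sign", "unspecified")
        if sign not in SIGNS:
            raise SchemaError(f"{ep}/sign",
                              f"unknown sign {sign!r}; expected one of "
                              f"{list(SIGNS)}")
        for role, val in (("source", src), ("target", tgt)):
            if val not in node_set:
                raise SchemaError(f"{ep}/{role}",
                                  f"undeclared node {val!r}")
        regs.append(Regulation(src, tgt, sign))
    inp = _require(obj, "input", str, pointer)
    out = _require(obj, "output", str, pointer)
    for role, val in (("input", inp), ("output", out)):
        if val not in node_set:
            raise SchemaError(f"{pointer}/{role}", f"undeclared node {val!r}")
    return Network(tuple(nodes), tuple(regs), inp, out)


def network_to_obj(net: Network) -> dict:
    return {
        "nodes": list(net.nodes),
        "edges": [{"source": r.source, "target": r.target, "sign": r.sign}
                  for r in net.regulations],
        "input": net.input,
        "output": net.output,
    }


def read_network(path) -> Network:
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError("/", f"invalid JSON: {exc}") from exc
    return network_from_obj(obj)


def write_network(net: Network, path) -> None:
    Path(path).write_text(json.dumps(network_to_obj(net), indent=2) + "\n")


# -- model files (network + kinetics + parameters) ---------------------------

def write_model(model, path) -> None:
    """Serialize a fixture/model: network plus per-node law descriptions."""
    obj = network_to_obj(model.network)
    obj["kinetics"] = {}
    for node in model.network.nodes:
        law: RateLaw = model.laws[node]
        entry = {
            "class": law.kinetics_class,
            "form": law.form,
            "params": dict(sorted(law.params.items())),
        }
        if law.exponents:
            entry["exponents"] = {k: v for k, v in law.exponents}
        obj["kinetics"][node] = entry
    Path(path).write_text(json.dumps(obj, indent=2) + "\n")


def read_model(path):
    """Read a model file back into (Network, laws dict)."""
    from .kinetics import make_rate_law
    with open(path) as fh:
        obj = json.load(fh)
    net = network_from_obj(obj)
    kin = _require(obj, "kinetics", dict, "")
    laws = {}
    for node in net.nodes:
        if node not in kin:
            raise SchemaError(f"/kinetics/{node}", "missing kinetics entry")
        entry = kin[node]
        ep = f"/kinetics/{node}"
        cls = _require(entry, "class", str, ep)
        params = _require(entry, "params", dict, ep)
        regs = [(s, net.sign_of(s, node)) for s in net.regulators_of(node)]
        law = make_rate_law(node, cls, regs, params,
                            stimulus=(node == net.input),
                            form=entry.get("form"))
        if entry.get("exponents"):
            from dataclasses import replace
            law = replace(law, exponents=tuple(sorted(
                entry["exponents"].items())))
        laws[node] = law
    return net, laws


# -- other exports -----------------------------------------------------------

def export_graphml(net: Network, path) -> None:
    g = nx.DiGraph()
    for n in net.nodes:
        role = []
        if n == net.input:
            role.append("input")
        if n == net.output:
            role.append("output")
        g.add_node(n, role="+".join(role), is_input=n == net.input,
                   is_output=n == net.output)
    for r in net.regulations:
        g.add_edge(r.source, r.target, sign=r.sign)
    nx.write_graphml(g, path)


def write_terms(eq: RPAEquation, path) -> None:
    """JSON-lines export of the term set **R** (one record per term)."""
    with open(path, "w") as fh:
        for t in eq.terms:
            fh.write(json.dumps({
                "sign": t.sign,
                "route": list(t.route),
                "circuits": [list(c) for c in sorted(t.circuits)],
                "multipliers": sorted(t.multipliers),
            }) + "\n")
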