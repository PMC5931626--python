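"""Canonical rate laws, ODE assembly, steady states, and adaptation metrics.

This is the numerical counterpart of the topological analysis: given a
network plus a kinetics assignment it builds the ODE system, drives it
through a stepped-input protocol, and checks whether the output returns to a
fixed set point (robust perfect adaptation) at every input level.

Kinetics classes
----------------
``generic``
    Mass-action-like: production ``kp * prod(activators) / prod(inhibitors)``
    (times the stimulus *I* on the input node), removal ``kd * x``.
``opposer``
    Zero-order in its own substrate: ``ka * prod(act) - kb * prod(inh) * g(x)``
    where ``g(x) = x / (x + eps)`` is a positivity guard with ``eps`` far
    below every tolerance (exact zero-order: ``eps = 0``).  The node's
    diagonal Jacobian entry vanishes at steady state, annihilating every
    RPA-equation term carrying its kinetic multiplier.  The ``annihilation``
    form ``ka * prod(act) - kb * x * prod(inh)`` implements mutual-
    annihilation pairs (antithetic integral feedback).
``balancer``
    Strictly linear in its single regulator: ``kb1 * R - kb2 * x``, pinning
    the steady state to a flat manifold (a linear function of the diverter's
    steady state).  The ``quadratic_removal`` form breaks the linearity on
    purpose (negative control).
``connector``
    ``kc1 * prod(act) - kc2 * prod(inh) * x``: the removal tracks the
    diverter (directly or through a balancer branch), cancelling the input
    dependence of the production so the connector's steady state is free of
    the D-node.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .network import Network

__all__ = [
    "RateLaw",
    "ODESystem",
    "SimulationProtocol",
    "SteadyState",
    "StepResponse",
    "AdaptationReport",
    "SweepSummary",
    "KineticsError",
    "make_rate_law",
    "find_steady_state",
    "run_step_protocol",
    "adaptation_metrics",
    "robustness_sweep",
]

KINETICS_CLASSES = ("opposer", "balancer", "connector", "generic")
DEFAULT_GUARD_EPS = 1e-12
_FLOOR = 1e-30  # division floor; states this small are already non-physical


class KineticsError(ValueError):
    """Kinetics class incompatible with the node's regulatory topology."""


@dataclass(frozen=True)
class RateLaw:
    """Rate law for one node: f(node states, stimulus I) -> dx/dt."""

    node: str
    kinetics_class: str
    form: str
    params: dict
    activators: tuple = ()
    inhibitors: tuple = ()
    stimulus: bool = False  # production multiplied by the input I
    guard_eps: float = DEFAULT_GUARD_EPS
    exponents: tuple = ()  # per-regulator power-law orders (form "power")

    def _orders(self) -> dict:
        return dict(self.exponents)

    def rate(self, values: dict, I: float) -> float:
        x = values[self.node]
        if self.form == "power" and self.exponents:
            h = self._orders()
            prod_a = math.prod(values[a] ** h.get(a, 1.0)
                               for a in self.activators)
            prod_i = math.prod(values[b] ** h.get(b, 1.0)
                               for b in self.inhibitors)
        else:
            prod_a = math.prod(values[a] for a in self.activators)
            prod_i = math.prod(values[b] for b in self.inhibitors)
        if self.stimulus:
            prod_a *= I
        p = self.params
        if self.kinetics_class == "generic":
            return p["kp"] * prod_a / max(prod_i, _FLOOR) - p["kd"] * x
        if self.kinetics_class == "balancer":
            if self.form == "quadratic_removal":
                return p["kb1"] * prod_a - p["kb2"] * x * x
            return p["kb1"] * prod_a - p["kb2"] * x
        if self.kinetics_class == "connector":
            return p["kc1"] * prod_a - p["kc2"] * prod_i * x
        if self.kinetics_class == "opposer":
            if self.form == "annihilation":
                return p["ka"] * prod_a - p["kb"] * x * prod_i
            g = 1.0 if self.guard_eps == 0 else x / (x + self.guard_eps)
            return p["ka"] * prod_a - p["kb"] * prod_i * g
        raise KineticsError(f"unknown kinetics class {self.kinetics_class!r}")

    def scaled(self, factors: dict) -> "RateLaw":
        """Multiply each rate parameter by its factor (robustness sweeps)."""
        new = {k: v * factors.get(k, 1.0) for k, v in self.params.items()}
        return replace(self, params=new)


def make_rate_law(node: str, kinetics_class: str,
                  regulators: Sequence[tuple[str, str]], params: dict,
                  *, stimulus: bool = False, form: str | None = None,
                  guard_eps: float = DEFAULT_GUARD_EPS) -> RateLaw:
    """Build a canonical rate law from a node's signed regulator list.

    Activating (and unspecified) regulators join the production group,
    inhibiting regulators the removal/division group.  Topology checks:
    opposers need a production group to track; balancers exactly one linear
    regulator; connectors both groups (removal must track the diverter).
    """
    if kinetics_class not in KINETICS_CLASSES:
        raise KineticsError(f"unknown kinetics class {kinetics_class!r}")
    act = tuple(s for s, sign in regulators if sign != "inhibiting")
    inh = tuple(s for s, sign in regulators if sign == "inhibiting")
    if kinetics_class == "opposer" and form != "annihilation":
        # annihilation pairs may have constitutive production (no activator)
        if not act:
            raise KineticsError(
                f"opposer {node!r} has no regulator to track")
        if len(act) > 1:
            raise KineticsError(
                f"opposer {node!r} has {len(act)} independent regulators "
                "in its production group; exactly one is required")
    if kinetics_class == "balancer":
        if len(act) != 1 or inh:
            raise KineticsError(
                f"balancer {node!r} needs exactly one linear regulator")
    if kinetics_class == "connector" and (not act or not inh):
        raise KineticsError(
            f"connector {node!r} needs production and removal groups")
    for k, v in params.items():
        if v <= 0:
            raise KineticsError(f"parameter {k}={v} must be positive")
    return RateLaw(node, kinetics_class, form or "canonical", dict(params),
                   act, inh, stimulus, guard_eps)


@dataclass
class ODESystem:
    """A network together with a complete kinetics assignment."""

    network: Network
    laws: dict  # node id -> RateLaw

    def __post_init__(self) -> None:
        missing = set(self.network.nodes) - set(self.laws)
        if missing:
            raise KineticsError(f"no rate law for nodes {sorted(missing)}")
        for node, law in self.laws.items():
            used = set(law.activators) | set(law.inhibitors)
            regs = set(self.network.regulators_of(node))
            if used != regs:
                raise KineticsError(
                    f"law for {node!r} uses regulators {sorted(used)} but the "
                    f"network wires {sorted(regs)}")
        self.order = list(self.network.nodes)

    def kinetics_assignment(self) -> dict:
        return {n: self.laws[n].kinetics_class for n in self.order}

    def f(self, y: np.ndarray, I: float) -> np.ndarray:
        values = {n: max(v, 0.0) for n, v in zip(self.order, y)}
        return np.array([self.laws[n].rate(values, I) for n in self.order])

    def jacobian(self, y: np.ndarray, I: float) -> np.ndarray:
        n = len(y)
        J = np.empty((n, n))
        f0 = self.f(y, I)
        for k in range(n):
            h = 1e-7 * max(abs(y[k]), 1e-3)
            yk = y.copy()
            yk[k] += h
            J[:, k] = (self.f(yk, I) - f0) / h
        return J

    def scaled(self, factors_per_node: dict) -> "ODESystem":
        laws = {n: law.scaled(factors_per_node.get(n, {}))
                for n, law in self.laws.items()}
        return ODESystem(self.network, laws)

    def param_index(self) -> list[tuple[str, str]]:
        """Stable (node, param name) enumeration for sweeps."""
        out = []
        for n in self.order:
            for k in sorted(self.laws[n].params):
                out.append((n, k))
        return out


@dataclass(frozen=True)
class SimulationProtocol:
    """Stepped-input protocol: hold each level until steady state."""

    levels: tuple = (0.2, 0.4, 0.6, 0.8, 1.0)
    hold: float = 50.0
    residual_tol: float = 1e-10
    adapt_tol: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.levels)) < 2:
            raise ValueError("protocol needs >= 2 distinct input levels")
        if any(l <= 0 for l in self.levels):
            raise ValueError("input levels must be positive")

    @classmethod
    def from_string(cls, spec: str, **kw) -> "SimulationProtocol":
        """Parse ``start:stop:step`` (e.g. ``0.2:1.0:0.2``)."""
        start, stop, step = (float(tok) for tok in spec.split(":"))
        n = int(round((stop - start) / step)) + 1
        levels = tuple(round(start + i * step, 12) for i in range(n))
        return cls(levels=levels, **kw)


@dataclass(frozen=True)
class SteadyState:
    input_level: float
    values: dict  # node -> steady-state value
    residual: float
    converged: bool
    jacobian_nonsingular: bool


@dataclass
class StepResponse:
    system: ODESystem
    protocol: SimulationProtocol
    steady_states: list
    trajectory: pd.DataFrame | None = None


@dataclass
class AdaptationReport:
    set_point: float
    precision: float
    node_precision: dict
    rpa_flags: dict  # node -> bool (steady state input-invariant)
    passed: bool
    excluded_levels: tuple = ()
    peak_deviation: float | None = None  # transient sensitivity, informative


@dataclass
class SweepSummary:
    n_draws: int
    n_converged: int
    n_passed: int
    set_points: list
    seed: int

    @property
    def pass_fraction(self) -> float:
        """Fraction of converged draws passing the RPA check."""
        if self.n_converged == 0:
            return float("nan")
        return self.n_passed / self.n_converged


class _BudgetExceeded(Exception):
    """Integration work budget blown: treat the window as unconverged."""


def _budgeted(system: ODESystem, I: float, budget: int = 100_000):
    count = [0]

    def f(t, v):
        count[0] += 1
        if count[0] > budget:
            raise _BudgetExceeded
        return system.f(v, I)

    return f


def _nonsingular(J: np.ndarray) -> bool:
    n = J.shape[0]
    if n == 0:
        return True
    scale = np.prod([max(np.max(np.abs(J[i])), 1e-12) for i in range(n)])
    return abs(np.linalg.det(J)) > 1e-12 * scale


def _newton_polish(system: ODESystem, I: float, y: np.ndarray,
                   tol: float, iters: int = 30) -> np.ndarray:
    """Damped Newton refinement: hybr can stall above the residual tolerance
    when rate constants push the system far from unit scale."""
    best = y.copy()
    best_res = float(np.max(np.abs(system.f(best, I))))
    for _ in range(iters):
        if best_res < tol * 1e-2:
            break
        J = system.jacobian(best, I)
        try:
            step = np.linalg.solve(J, -system.f(best, I))
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        improved = False
        for _ in range(8):
            cand = best + lam * step
            if np.all(np.isfinite(cand)) and np.all(cand > 0):
                res = float(np.max(np.abs(system.f(cand, I))))
                if res < best_res:
                    best, best_res = cand, res
                    improved = True
                    break
            lam *= 0.5
        if not improved:
            break
    return best


def find_steady_state(system: ODESystem, I: float, x0=None, *,
                      residual_tol: float = 1e-10, hold: float = 50.0,
                      max_windows: int = 40,
                      method: str = "dynamic") -> SteadyState:
    """Steady state at stimulus ``I``.

    ``dynamic`` integrates from ``x0`` until the residual is small, then
    root-polishes, biasing the answer toward the dynamically reached branch;
    ``direct`` skips integration (used by large topology screens).  Non-
    convergence and non-positive states are reported via flags, not raised.
    """
    if I <= 0:
        raise ValueError("stimulus I must be positive")
    y = (np.ones(len(system.order)) if x0 is None
         else np.asarray(x0, dtype=float))
    ok_dynamic = False
    if method == "dynamic":
        prev_res = np.inf
        for _ in range(max_windows):
            try:
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.filterwarnings("ignore", message="lsoda")
                    sol = solve_ivp(_budgeted(system, I), (0.0, hold), y,
                                    method="LSODA", rtol=1e-9, atol=1e-11,
                                    t_eval=(0.0, hold))
            except _BudgetExceeded:
                break
            if not sol.success or not np.all(np.isfinite(sol.y[:, -1])):
                break
            y = np.maximum(sol.y[:, -1], _FLOOR)
            if np.max(y) > 1e12:
                break  # diverging: no reachable steady state
            res = float(np.max(np.abs(system.f(y, I))))
            if res < 1e-7:
                ok_dynamic = True
                break
            if res > 0.99 * prev_res and res > 1e-3:
                break  # not contracting
            prev_res = res
    if not np.all(np.isfinite(y)):
        y = np.ones(len(system.order))
    with np.errstate(all="ignore"):
        polished = root(lambda v: system.f(v, I), y, method="hybr",
                        options={"xtol": 1e-13})
    if polished.success and np.all(np.isfinite(polished.x)):
        y_fin = _newton_polish(system, I, polished.x, residual_tol)
        res = float(np.max(np.abs(system.f(y_fin, I))))
        positive = bool(np.all(y_fin > 0))
        converged = res < residual_tol and positive
        if method == "dynamic" and not ok_dynamic and converged:
            # root exists but dynamics never approached it: check it is at
            # least locally attracting before accepting
            eigs = np.linalg.eigvals(system.jacobian(y_fin, I))
            converged = bool(np.all(eigs.real < 1e-8))
    else:
        y_fin, res, converged = y, float(np.max(np.abs(system.f(y, I)))), False
    J = system.jacobian(np.maximum(y_fin, _FLOOR), I)
    return SteadyState(I, dict(zip(system.order, y_fin)), res, converged,
                       _nonsingular(J))


def run_step_protocol(system: ODESystem, protocol: SimulationProtocol, *,
                      record: bool = True,
                      method: str = "dynamic") -> StepResponse:
    """Hold each input level to convergence, chaining initial conditions."""
    states: list[SteadyState] = []
    frames = []
    y = np.ones(len(system.order))
    t_offset = 0.0
    for level in protocol.levels:
        if record:
            try:
                with np.errstate(all="ignore"), warnings.catch_warnings():
                    warnings.filterwarnings("ignore", message="lsoda")
                    sol = solve_ivp(_budgeted(system, level),
                                    (0.0, protocol.hold), y, method="LSODA",
                                    rtol=1e-9, atol=1e-11, dense_output=False,
                                    max_step=protocol.hold / 50)
            except _BudgetExceeded:
                sol = None
            if sol is not None and sol.success:
                frame = pd.DataFrame(sol.y.T, columns=system.order)
                frame.insert(0, "time", sol.t + t_offset)
                frame.insert(1, "input", level)
                frames.append(frame)
                t_offset += protocol.hold
                y = np.maximum(sol.y[:, -1], _FLOOR)
        ss = find_steady_state(system, level, y,
                               residual_tol=protocol.residual_tol,
                               hold=protocol.hold, method=method)
        states.append(ss)
        if ss.converged:
            y = np.array([ss.values[n] for n in system.order])
    traj = pd.concat(frames, ignore_index=True) if frames else None
    return StepResponse(system, protocol, states, traj)


def adaptation_metrics(result: StepResponse,
                       tol: float | None = None) -> AdaptationReport:
    """Adaptation precision: worst relative deviation of the output steady
    state from its value at the reference (first converged) level."""
    tol = result.protocol.adapt_tol if tol is None else tol
    system = result.system
    out_node = system.network.output
    ok = [s for s in result.steady_states if s.converged]
    excluded = tuple(s.input_level for s in result.steady_states
                     if not s.converged)
    if len(ok) < 2:
        raise ValueError(
            f"adaptation metrics need >= 2 converged steady states "
            f"(got {len(ok)}; unconverged levels: {list(excluded)})")
    ref = ok[0]
    node_precision = {}
    for n in system.order:
        base = abs(ref.values[n])
        dev = max(abs(s.values[n] - ref.values[n]) for s in ok)
        node_precision[n] = dev / base if base > 0 else float("inf")
    rpa_flags = {n: node_precision[n] <= tol for n in system.order}
    precision = node_precision[out_node]
    passed = (precision <= tol and not excluded
              and all(s.jacobian_nonsingular for s in ok))
    peak = None
    if result.trajectory is not None and len(result.trajectory) > 1:
        out = result.trajectory[out_node].to_numpy()
        peak = float(np.max(np.abs(out - ref.values[out_node]))
                     / abs(ref.values[out_node]))
    return AdaptationReport(ref.values[out_node], precision, node_precision,
                            rpa_flags, passed, excluded, peak)


def robustness_sweep(system: ODESystem, n_draws: int, *,
                     factor_range: tuple = (0.1, 10.0), seed: int = 0,
                     protocol: SimulationProtocol | None = None,
                     method: str = "dynamic") -> SweepSummary:
    """Rerun the step protocol with every rate parameter independently
    rescaled by a log-uniform factor.  Adaptation must persist although the
    set point may move; the summary counts converged draws that still pass.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    protocol = protocol or SimulationProtocol()
    rng = np.random.default_rng(seed)
    lo, hi = math.log(factor_range[0]), math.log(factor_range[1])
    index = system.param_index()
    n_converged = n_passed = 0
    set_points = []
    for _ in range(n_draws):
        draws = np.exp(rng.uniform(lo, hi, size=len(index)))
        factors: dict = {}
        for (node, key), val in zip(index, draws):
            factors.setdefault(node, {})[key] = float(val)
        trial = system.scaled(factors)
        try:
            resp = run_step_protocol(trial, protocol, record=False,
                                     method=method)
            report = adaptation_metrics(resp)
        except ValueError:
            continue  # too few converged levels: draw excluded
        if report.excluded_levels:
            continue  # draw only counts as converged if every level did
        n_converged += 1
        if report.passed:
            n_passed += 1
            set_points.append(report.set_point)
    return SweepSummary(n_draws, n_converged, n_passed, set_points, seed)
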