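# Methods

## The model

`rpatopo` analyzes robust perfect adaptation (RPA): the property of a
signaling network whose output steady state returns to a fixed set point
after any persistent change in the input stimulus *I*, without parameter
tuning. For a network of *n* species `P_1..P_n` with rates `f_1..f_n`,
RPA relative to a chosen input/output node pair requires, at steady state
and for all *I*,

```
det(M_IO) = 0   and   det(J_n) != 0
```

where `J_n = d(f_1..f_n)/d(P_1..P_n)` and `M_IO` is the minor of `J_n`
with the input **row** and output **column** removed (when input and output
coincide, the principal minor deleting that node). The first condition is
the RPA equation; the second guarantees a well-defined, non-degenerate
steady state.

### Term anatomy

The permutation expansion of `det(M_IO)` is treated as a set **R** of signed
terms. Because `M_IO[i, k]` is structurally nonzero only when the network
wires `k -> i` (or `i == k`), every surviving permutation decomposes into

1. a **route factor** — a simple directed path from input to output,
2. **circuit products** — vertex-disjoint simple cycles (feedback loops), and
3. **kinetic multipliers** — diagonal entries `d f_k / d P_k` on every node
   not used by the route or a circuit.

`expand_rpa_equation` enumerates these structures directly from the graph;
the term sign is computed from the parity of the row/column bijection rather
than a hand-derived path/cycle rule, and the whole expansion is verified in
tests against an independent cofactor-expansion determinant (symbolically
for n <= 6, numerically under random substitution for n <= 8). The default
node cap is 12 (`tau` can reach 11! there); `max_term_count(n) = (n-1)!` is
the fully connected bound.

Symbols are named `j_<target>_<source>` for `d f_target / d P_source`.
Node ids containing underscores are legal but make the flat symbol names
ambiguous to read back; the labeled `MinorMatrix` is the authoritative
mapping.

### Independently adapting subsets and the two mechanisms

**R** must be partitionable into subsets that each sum to zero for all *I*.
Two mechanisms exist:

* **Opposition (S-sets).** A term dies because one of its kinetic
  multipliers vanishes at steady state: an *opposer* node with
  `d f_o / d P_o = 0` for all *I* (zero-order kinetics in its own
  substrate — an integrator of a tracking error). An opposer must sit in a
  feedback loop and, as a lone opposer, have a single independent regulator
  sharing a circuit with it. A single opposer fully opposes a route iff it
  is disjoint from the route and participates only in circuits contiguous
  with it (sharing >= 1 node). Collections of opposers ("opposing sets")
  spread over interlinked circuits can fully oppose routes that no single
  member could.
* **Balancing (M-sets).** Terms spanning at least two distinct routes cancel
  with strictly nonzero values. Topologically: parallel route segments
  diverge at a diverter node D and reconnect at a connector node C; the
  interior nodes are *balancers*, whose kinetics pin their steady states to
  a flat manifold (linear functions of D's steady state); the connector's
  kinetics then cancel the input dependence, so the connector alone
  exhibits RPA. Balancing requires >= 2 distinct routes, so a network whose
  input node is also its output cannot balance and must rely on opposition.

A topology is RPA-capable iff every route is either balanced or fully
opposed by exactly one module, modules' kinetics roles are mutually
exclusive node-wise, and live outgoing regulations (from non-RPA nodes of a
module) are themselves covered by ancillary modules downstream — the series
rule. Outgoing regulations from RPA nodes are blind and unconstrained.

## Interpretive choices (where the formal statements were not available)

The formal statements of the opposing-set and balancer-module theorems and
the precise definitions of "connected" and "transmissive" live in material
not reproduced here; the implementation reconstructs them from the
narrative and the worked examples. These are the package's operative
definitions, and they are deliberately conservative:

* **Pruning** keeps nodes on routes, then transitively absorbs whole
  circuits sharing a node with the kept set. This is an inference from the
  route/circuit/multiplier term anatomy: a node outside every route and
  every route-chained circuit can only enter **R** through its kinetic
  multiplier and cannot shape which subsets exist.
* **Opposing sets**: a connected collection of circuits disjoint from the
  opposed route, with exactly one *designated* opposer per circuit (one
  node may serve adjacent circuits, as in chained sets); the master set
  (union of those circuits) must have exactly one external independent
  regulator, and that regulation must feed a designated opposer; the set
  must additionally be embedded in some circuit contiguous with the route.
  A single 2-cycle may have both members designated — the
  mutual-annihilation pattern, which is how antithetic integral feedback
  appears as a two-node opposing set around a single input/output node.
  Results are master-set minimal. Interlinked collections are capped at 4
  circuits (combinatorial guard; sufficient for all shipped fixtures).
* **Balancer modules**: all diverter/connector pairs with >= 2 route
  segments (at least one internally node-disjoint pair), whose segment
  interiors — plus any feedback loop that can be absorbed without touching
  route nodes — have the diverter as sole independent regulator. One extra
  structural constraint is imposed: a circuit confined to
  balancers + {D, C} must lie wholly inside the balancer set. This rejects
  diverter<->balancer feedback pairs (no flat manifold is possible when the
  diverter is driven by its own balancer) while still admitting long
  feedback loops that exit the module.
* **Decomposition identity**: decompositions are enumerated per *module
  set*. Route assignment is canonical — a balancer module automatically
  absorbs every route through its D->C segments (balancing is automatic for
  all copies of its routes, and partially opposed routes fold into the same
  subsets), remaining routes go to the first covering opposer module in
  deterministic order. Subsets with an idle module are dropped as
  redundant. A decomposition is reported only if the output node ends up
  with the RPA property (module-marked nodes closed under dependents, with
  opposers/balancers/diverters barred from the closure).

A consequence worth knowing: networks can admit *more* valid decompositions
than the ones a figure highlights (e.g. interior route nodes that sit in a
feedback loop with a single regulator are legitimate opposer candidates).
The enumeration returns all of them, none preferred.

## Canonical rate laws

One representative rate law per kinetics class (the admissible
chemical-reaction families are broader; these are the canonical members):

| class | form | steady-state consequence |
|---|---|---|
| generic | `kp * prod(act)/prod(inh) - kd * x` (stimulus multiplies production on the input node) | none (baseline) |
| opposer | `ka * prod(act) - kb * prod(inh) * x/(x+eps)` | `prod(act)/prod(inh)` pinned to `kb/ka` |
| opposer, annihilation form | `ka * prod(act) - kb * x * prod(inh)` | mutual-annihilation integrator pairs |
| balancer | `kb1 * R - kb2 * x` (single regulator R) | `x* = (kb1/kb2) R*` — the flat manifold |
| connector | `kc1 * prod(act) - kc2 * prod(inh) * x` | `x*` free of the diverter when the act/inh groups track it equally |

The opposer's positivity guard `x/(x + eps)` prevents negative
concentrations while keeping `d f_o / d P_o ~ eps/x^2` far below every
tolerance. `eps = 1e-12` by default: under log-uniform parameter sweeps with
factors in [0.1, 10] the opposer's set-point offset scales like `eps/O*`,
and `O*` can legitimately fall to ~1e-5, so the guard must sit several
orders below the 1e-6 adaptation tolerance. Exact zero-order removal is
available via `guard_eps=0`.

## Numerics

* **Steady states**: integrate (LSODA, rtol 1e-9/atol 1e-11) in windows of
  the protocol hold time until the residual contracts below 1e-7, then
  root-polish (Powell hybrid) and finish with damped Newton; converged
  means residual < 1e-10 with strictly positive state. If the dynamics
  never approached the root, it is accepted only when locally attracting
  (eigenvalue check) — steady states are biased toward the dynamically
  reachable branch, and multistability is not resolved. Each window carries
  a 1e5 right-hand-side evaluation budget so structurally steady-state-free
  systems (the negative controls) fail fast instead of grinding.
* **Nonsingularity** (`det(J_n) != 0`): |det| > 1e-12 relative to the
  product of row magnitudes.
* **Step protocol**: input levels 0.2, 0.4, 0.6, 0.8, 1.0 held for 50 time
  units each (`start:stop:step` strings accepted), chaining initial
  conditions level to level. Adaptation precision is the worst relative
  deviation of the output steady state from the first converged level; pass
  means precision <= 1e-6 (configurable) with every level converged and
  nonsingular. Transient peak deviation is reported but never gates
  pass/fail (no threshold is defined for it).
* **Robustness sweeps** multiply every rate parameter by an independent
  log-uniform factor (default range [0.1, 10], seeded, bit-reproducible)
  and re-run the protocol; a draw counts as converged only when every level
  converged, and the summary reports the passing fraction of converged
  draws. Set points are expected to move; adaptation is not.

## The topology screen and what it does (not) show

`scan.coincident_topologies(4)` enumerates all 299
connected-and-transmissive topologies on up to 4 nodes whose input node is
also the output (one representative per isomorphism class with the input
fixed). `scan.screen_rpa` is detector-independent: it tries the all-generic
assignment plus opposer kinetics at each node with a single regulator, 20
log-uniform parameter draws each, solving steady states algebraically at
three input levels.

Generic laws in the screen use random power-law interaction orders (drawn
log-uniformly from [0.5, 2] per edge per draw). This matters: with every
interaction exactly first-order, a circuit product can cancel the
complementary kinetic-multiplier product *identically in the parameters*
(the cancellation condition becomes an integer-coefficient identity in log
space), scoring topologies as adapting through a degeneracy of that one
rate-law family rather than through integral control. Random orders break
the degeneracy; opposer-driven adaptation survives arbitrary orders because
the zero-order integrator pins its tracked quantity regardless.

The screen also rejects steady states below 1e-8: the all-off state is
always a fixed point of regulator-driven production and an algebraic solver
will happily land on it.

Because the screen solves steady states algebraically, it certifies
*steady-state* adaptation, not global dynamic stability; fixtures are
additionally simulated dynamically.

## Fixtures

`fig2a` and `fig2b` implement the printed minimal models and parameters
verbatim; their set points follow in closed form (`X* = k2/k1 = 0.5`,
`C* = k1*k3/(k2*k4) = 0.4`). All other fixtures are reconstructions: the
source figures specify node roles but not edge lists or equations, so each
builder documents its assumed wiring, and every positive fixture is
required by the test suite to (a) adapt numerically at 1e-6 and (b) have
its kinetics roles appear among the topologically enumerated
decompositions. Rate constants were chosen for positivity and for local
stability across the protocol's input range (integrator gains are lowered
where long feedback chains would otherwise cross a Hopf bifurcation —
e.g. the seven-node master-set chain). The fig8-family fixtures use 6–8
nodes; they demonstrate the named structural features and make no
minimality claim.

## Known limitations

* Opposing-set and balancer conditions are reconstructions (above); exotic
  arrangements beyond 4 interlinked circuits are not searched.
* Decomposition search is exhaustive over candidate-module subsets
  (exponential worst case; guarded at 16 candidates). Intended scale is
  <= ~15 nodes.
* No oscillation/chaos analysis: non-convergent dynamics are flagged, not
  characterized. Stability is checked locally at steady states only.
* Single input/output pair per analysis; loop over pairs externally.
* Stochastic kinetics, reaction-diffusion extensions, and rate-parameter
  design/fitting are out of scope.
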