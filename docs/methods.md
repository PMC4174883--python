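# Methods

This note records the semantics `lemsim` implements, the numerical choices
behind them, and the places where the language description leaves room
that required a design decision.

## Dimensions, units and quantities

A dimension is a named 7-tuple of integer exponents over the SI base
dimensions in the fixed canonical order (mass, length, time, current,
temperature, amount, luminous intensity).  Documents may declare base
exponents in any order; they are normalized on load so that equality is
plain exponent-tuple equality, independent of names.  Non-integer
exponents are rejected: no in-scope model needs them and integer
arithmetic keeps checking exact.

Units convert by `si = value · scale · 10^power10 + offset`.  Offset
(affine) units such as Fahrenheit are legal only in direct parameter
assignment: they are barred from compound unit definitions and from
expressions because affine units break the linearity dimension algebra
relies on.  Unit symbols are case-sensitive (`mV` ≠ `MV`; SI prefixes
collide under case folding).  Units and constants may reference dimensions
declared later in a document: registries are filled in a first pass, so
forward references resolve after load.

## The expression grammar

Expressions are C-like with Fortran-spelled relational/logical operators
(`.lt.`, `.gt.`, `.leq.`, `.geq.`, `.eq.`, `.neq.`, `.and.`, `.or.`;
`.le.`/`.ge.` accepted as input aliases).  Precedence, loosest first:
`.or.` < `.and.` < relational < `+ -` < `* /` < unary minus < `^`
(right-associative).  Built-ins: exp, log (natural), ln, sqrt, sin, cos,
tan, sinh, cosh, tanh, abs, ceil, floor, and `random(x)` — uniform on
[0, x) from the per-run seeded generator, so that any run is reproducible
from (document, seed, method, dt).

Booleans never escape conditions: a relational operator inside arithmetic
is a parse-time error, which keeps dimension inference total over
arithmetic nodes.  Dimension rules: `+`/`-` and relationals require equal
operand dimensions; `*`/`/` combine exponent-wise; `^` needs an
integer-literal exponent when the base is dimensional; transcendentals
require and return dimensionless.

**Singularity guard.**  The exponential-linear rate form
`x / (1 − e^(−x))` has a removable singularity at 0.  The parser
recognizes the pattern structurally (the numerator equals the negation of
the `exp` argument) and rewrites it into a dedicated node that evaluates
the two-term Taylor form `1 + x/2` for |x| < 1e-7 and the exact form
elsewhere.  At the guard boundary the two forms differ by O(1e-15), so the
function stays continuous and monotone across 0 (tested on a grid over
[−10, 10]).

## Documents

The root element admits exactly seven child kinds: Target, Include,
Dimension, Unit, Constant, ComponentType, Component.  Components may be
written `<Component type="T"/>` or with the type name as the tag; both
normalize identically.  Includes resolve depth-first against the including
file's directory then the configured search paths, each physical file
loaded at most once, with cycle detection.  Element order in a file is
unconstrained beyond containment.  XML namespaces are ignored (local names
only).  Anonymous nested components receive stable synthetic ids
(`parentId_elementName_ordinal`) so traces and error messages can address
them.  Serialization emits the merged document (includes already resolved,
with a provenance comment) and round-trips structurally.

The `Simulation` element (step, length, target, Display/Line,
OutputFile/OutputColumn children) is treated as a built-in component kind
interpreted by the engine rather than requiring a ComponentType
declaration, mirroring reference-interpreter practice.

## Types, components, checking

Type resolution merges the extension chain base-first.  A derived type may
add members and may override an inherited DerivedVariable or
TimeDerivative by redeclaring the name; parameters and exposures may never
change dimension (silent dimension changes would defeat checking).  A
component of type T fills any child slot declared with an ancestor of T;
`Child` slots require exactly one occupant, `Children` any number.

Requirements are matched **by exposure name**, nearest ancestor first.
Derived variables may instead be selections over a child or attachment
collection with `add` or `multiply` reduction; empty collections reduce to
the identity (0 / 1).  Multiply-reduction is needed because a channel's
open fraction is the product of its gates' open probabilities.
DerivedParameters may reference only parameters and constants and are
evaluated once at build.

`check_dynamics` verifies every TimeDerivative against dim(state)/time,
every DerivedVariable and StateAssignment against its declared target
dimension, and every condition against like-dimension comparisons; all
violations are collected into one report (a non-empty report blocks
simulation).  When regimes exist, exactly one must carry `initial="true"`.

## Building and events

Instantiation is depth-first: state variables start at 0, kinetic-scheme
occupancies start with the first declared state at 1 and the rest at 0,
then OnStart assignments run in pre-order document order (so a cell's
initial potential is visible to its gates' steady-state initialization),
then each multi-regime instance enters its initial regime and runs its
OnEntry.

`MultiInstantiate` expands a population into independent instances named
`refId[k]`; event-connection receivers instantiate onto the target's
attachment slot as `slot[k]` in creation order (document order of
connections).  EventConnection endpoint attributes name Text/Parameter
fields of the declaring component when such fields exist, otherwise they
are literal instance paths; paths resolve relative to the declaring
instance, then its parent, and the tokens `parent`/`this` support the
synapse-to-plasticity-mechanism relay.  A source port may be an *in* port,
meaning events received on it are forwarded onward — delivery to the
owner's handlers happens before zero-delay forwarding, so a synapse reads
its plasticity factor before the mechanism's spike update.  Delay defaults
to 0 and weight to 1; the weight reaches the receiving handler as the
reserved symbol `weight`.

The event queue orders by (delivery time, insertion sequence); an event
emitted at t with delay d is delivered at the first step boundary at or
after t + d, FIFO among equal times.  Sub-step event location is out of
scope for fixed-step integration.

## Stepping

Update order within a step: (1) ODE update of active-regime states,
(2) event delivery and OnEvent handlers (zero-delay relays drained in the
same pass), (3) OnCondition edge detection — a handler fires only on a
false→true transition relative to the previous step, with handlers
processed in document order, (4) OnEntry of a newly entered regime (inside
the transition; newly active handlers are primed with their current truth
value so a condition already true on entry does not fire without a
crossing), (5) derived variables recomputed, (6) recording.  Conditions
are also primed at t = 0 after initialization.

Per-regime derivatives override same-named top-level ones; a state with no
derivative in the active regime is frozen (this is how the refractory
regime holds v).  Kinetic-scheme occupancies evolve by mean-field flux
(d occ/dt = Σ in − Σ out over edges' forward/reverse rate exposures) and
are clipped to [0, 1] and renormalized to sum 1 after every step to guard
fixed-step drift; stochastic trajectory sampling of the scheme is out of
scope.  The simulation time `t` is available in every scope with dimension
time.

Flattening lays the state out as ordered (instance path, state name)
pairs.  The flat derivative function writes the vector back through the
tree, so scoped requirements bind to exactly the ancestor slots the tree
walk uses, and cycles among derived variables are rejected at flatten
time.  Euler on the flattened vector and Euler on the tree agree to within
1e-9 relative at every step (bitwise, in practice).  RK4 evaluates derived
variables and requirements at each internal stage; events and conditions
are processed at step boundaries only.  The default method is RK4 on the
flattened system; the tree-walk Euler is retained as the independent
execution oracle and as the CLI's `euler` fallback semantics.

Non-finite states abort the run naming the offending variable path.
Traces record every step in SI units; output files are TSV with time in
seconds at full float precision, and repeated runs with the same seed are
byte-identical.

## The fixture catalog and what it does (not) show

Fixture parameters are stated study conditions, chosen once:

* `hh_cell` uses the classic 1952 squid-axon parameterization on a 1 cm²
  patch (C = 1 µF, ḡ_Na = 120 mS, ḡ_K = 36 mS, ḡ_leak = 0.3 mS,
  E_Na = 50 mV, E_K = −77 mV, E_leak = −54.387 mV; the six standard rate
  functions with their usual midpoints/scales), driven by a 10 µA step at
  50 ms; spike events are emitted on upward crossings of 0 mV.
* `adex_cell` uses the reference regular-spiking set (C = 281 pF,
  g_L = 30 nS, E_L = V_r = −70.6 mV, V_T = −50.4 mV, Δ_T = 2 mV, a = 4 nS,
  b = 80.5 pA, τ_w = 144 ms) with a 2 ms refractory period.  Spike
  detection is at −40 mV ≈ V_T + 5Δ_T: past that point the exponential
  term guarantees divergence, and detecting there keeps the blow-up out of
  the RK4 stage evaluations at fixed step.
* `blocking_plastic_synapse` uses the standard magnesium-block sigmoid
  (scaling concentration 3.57 mM, scaling voltage 16.13 mV) and the
  two-variable depression/facilitation model (on each spike R ← R − U·R
  then U ← U + U₀(1 − U); between spikes R recovers with τ_rec, U decays
  with τ_fac).  The postsynaptic side is voltage-clamped at +100 mV so the
  conductance trace isolates the presynaptic dynamics.
* `small_network` is a 3-cell mutually inhibitory ring built from the
  above cell and synapse with 5 ms delays.  Its checks are property-based
  (it runs, conserves invariants and routes events); no sustained
  alternating rhythm is asserted, since the quantitative pyloric behavior
  depends on conductance sets outside this catalog's scope.

Simulation lengths and steps in the fixtures (50–300 ms at 0.01–0.1 ms)
are the catalog's own choices, sized so each run finishes in seconds while
the closed-form comparisons reach their stated tolerances.  Passing these
tests shows the *interpreter* is correct on models the language can
express; it does not calibrate any fixture against experimental data.

The random-network generator emulates network-scale stress (Bernoulli
connectivity, uniform delays/weights, identical cells); it deliberately
omits heterogeneous cell parameters, conductance-based coupling and
realistic topology, so results on generated networks validate event
routing and scaling, not network science.

## Known limitations

No piecewise expressions or user-defined functions; no variable-step or
implicit solvers; no sub-step event localization; no structural subtyping;
no stochastic kinetic-scheme trajectories; no spatial morphologies or
field equations; XML Schema validation is intentionally absent (the
interpreter is more permissive than a schema, accepting any element
order).  Components of a base type with no dynamics can be extended but
not simulated.
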