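"""Fixed-step simulation: Euler on the instance tree, Euler/RK4 on the
flattened system, hybrid event handling, and trace recording.

Update order within a step (the hybrid semantics are fixed-step; events and
condition crossings are located at step boundaries only):

1. ODE update of the active-regime state variables (kinetic-scheme
   occupancies included, then clipped to [0, 1] and renormalized to sum 1);
2. delivery of due events and their OnEvent handlers (zero-delay relays are
   drained in the same pass);
3. OnCondition edge detection — a handler fires only on a false-to-true
   transition relative to the previous step — with its assignments, event
   emissions and regime transition;
4. OnEntry of any newly entered regime (inside the transition);
5. derived variables recomputed;
6. recording.

RK4 evaluates derived variables and requirements at each internal stage;
its flattened state vector lays out (instance path, state name) pairs, and
evaluating the flat derivative at a state equals evaluating the instance
tree at the same state.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from . import expressions as ex
from . import runtime as rt
from .document import LemsDocument
from .semantics import (
    ConditionHandler,
    EventOut,
    SemanticError,
    StateAssign,
    Transition,
    check_document,
)
from .units import TIME, parse_quantity

__all__ = [
    "FlatSystem",
    "RecordedTraces",
    "SimulationSpec",
    "flatten",
    "simulate",
    "write_traces",
    "EngineError",
]


class EngineError(RuntimeError):
    """Simulation failure (non-finite state, unresolvable record path...)."""


# --------------------------------------------------------------------------
# Fast per-node expression evaluation


def _fast_eval(node: rt.InstanceNode, expr, extra: dict | None = None):
    fn, syms = ex.cached_compile(expr)
    if extra:
        bindings = {
            s: extra[s] if s in extra else rt.resolve_value(node, s) for s in syms
        }
    else:
        bindings = {s: rt.resolve_value(node, s) for s in syms}
    rng = node.root.rng if node.root else None
    return fn(bindings, rng)


# --------------------------------------------------------------------------
# Shared hybrid machinery (ODE right-hand side, events, conditions)


class _Hybrid:
    """Event/condition/derivative machinery over a built instance tree."""

    def __init__(self, root: rt.InstanceTreeRoot):
        self.root = root
        self.nodes = list(root.iter_nodes())
        self._prev_cond: dict[tuple[int, int], bool] = {}
        # nodes that own kinetic schemes
        self.kinetic_owners = [
            n for n in self.nodes if n.type.dynamics.kinetic_schemes
        ]

    def rebuild_node_list(self) -> None:
        self.nodes = list(self.root.iter_nodes())

    # -- derivatives -------------------------------------------------------

    def active_derivatives(self, node: rt.InstanceNode):
        dyn = node.type.dynamics
        if node.regime is None or not dyn.regimes:
            return dyn.time_derivatives
        merged = dict(dyn.time_derivatives)
        merged.update(dyn.regimes[node.regime].time_derivatives)
        return merged

    def compute_derivatives(self) -> list[tuple[rt.InstanceNode, str, float]]:
        out = []
        for node in self.nodes:
            for var, expr in self.active_derivatives(node).items():
                out.append((node, var, _fast_eval(node, expr)))
        for owner in self.kinetic_owners:
            out.extend(self._kinetic_derivatives(owner))
        return out

    def _kinetic_derivatives(self, owner: rt.InstanceNode):
        out = []
        for scheme in owner.type.dynamics.kinetic_schemes:
            states = owner.child_collection(scheme.nodes)
            index = {s.name: s for s in states}
            deriv = {s.name: 0.0 for s in states}
            for edge in owner.child_collection(scheme.edges):
                src = edge.component.texts.get(scheme.edge_source)
                dst = edge.component.texts.get(scheme.edge_target)
                if src not in index or dst not in index:
                    raise EngineError(
                        f"kinetic scheme {scheme.name!r} at {owner.path!r}: edge "
                        f"{edge.name!r} references unknown states {src!r}->{dst!r}"
                    )
                rf = rt.exposure_value(edge, scheme.forward_rate)
                rr = rt.exposure_value(edge, scheme.reverse_rate)
                occ_src = index[src].state[scheme.state_variable]
                occ_dst = index[dst].state[scheme.state_variable]
                flux = rf * occ_src - rr * occ_dst
                deriv[src] -= flux
                deriv[dst] += flux
            for sname, d in deriv.items():
                out.append((index[sname], scheme.state_variable, d))
        return out

    def renormalize_kinetics(self) -> None:
        """Clip occupancies to [0, 1] and renormalize each scheme to sum 1;
        guards forward-integration drift."""
        for owner in self.kinetic_owners:
            for scheme in owner.type.dynamics.kinetic_schemes:
                states = owner.child_collection(scheme.nodes)
                total = 0.0
                for s in states:
                    v = s.state[scheme.state_variable]
                    v = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
                    s.state[scheme.state_variable] = v
                    total += v
                if total > 0.0:
                    for s in states:
                        s.state[scheme.state_variable] /= total

    # -- events ------------------------------------------------------------

    def emit(self, node: rt.InstanceNode, port: str, t: float) -> None:
        self.root.event_log.append((t, node.path, port))
        for conn in node.out_connections.get(port, ()):
            self.root.queue.push(t + conn.delay, conn.target, conn.port, conn.weight)

    def deliver_events(self, now: float) -> None:
        queue = self.root.queue
        while queue.peek_time() is not None and queue.peek_time() <= now:
            for target, port, weight in queue.pop_due(now):
                self._handle_event(target, port, weight, now)

    def _handle_event(self, node: rt.InstanceNode, port: str, weight: float, now: float) -> None:
        dyn = node.type.dynamics
        handlers = [h for h in dyn.on_events if h.port == port]
        if node.regime is not None and dyn.regimes:
            handlers += [h for h in dyn.regimes[node.regime].on_events if h.port == port]
        for h in handlers:
            self.apply_actions(node, h.actions, now, extra={"weight": weight})
        for conn in node.in_forward.get(port, ()):
            self.root.queue.push(now + conn.delay, conn.target, conn.port, conn.weight)

    # -- conditions --------------------------------------------------------

    def active_conditions(self, node: rt.InstanceNode) -> list[ConditionHandler]:
        dyn = node.type.dynamics
        handlers = list(dyn.on_conditions)
        if node.regime is not None and dyn.regimes:
            handlers += dyn.regimes[node.regime].on_conditions
        return handlers

    def prime_conditions(self) -> None:
        """Record initial condition values so handlers already true at the
        start do not fire without a crossing."""
        for node in self.nodes:
            for h in self.active_conditions(node):
                key = (id(node), id(h))
                self._prev_cond[key] = bool(_fast_eval(node, h.test))

    def scan_conditions(self, now: float) -> None:
        for node in self.nodes:
            for h in self.active_conditions(node):
                key = (id(node), id(h))
                cur = bool(_fast_eval(node, h.test))
                prev = self._prev_cond.get(key, cur)
                self._prev_cond[key] = cur
                if cur and not prev:
                    self.apply_actions(node, h.actions, now)

    def apply_actions(self, node: rt.InstanceNode, actions, now: float,
                      extra: dict | None = None) -> None:
        for action in actions:
            if isinstance(action, StateAssign):
                value = _fast_eval(node, action.expr, extra)
                node.state[action.variable] = value
                self.root.bump_epoch()
            elif isinstance(action, EventOut):
                self.emit(node, action.port, now)
            elif isinstance(action, Transition):
                self._enter_regime(node, action.regime, now)

    def _enter_regime(self, node: rt.InstanceNode, regime: str, now: float) -> None:
        if regime not in node.type.dynamics.regimes:
            raise EngineError(f"{node.path!r}: unknown regime {regime!r}")
        node.regime = regime
        for assign in node.type.dynamics.regimes[regime].on_entry:
            node.state[assign.variable] = _fast_eval(node, assign.expr)
            self.root.bump_epoch()
        # newly active handlers start from their current truth value
        for h in node.type.dynamics.regimes[regime].on_conditions:
            self._prev_cond[(id(node), id(h))] = bool(_fast_eval(node, h.test))

    # -- post-ODE phases shared by all integrators --------------------------

    def finish_step(self, t_new: float) -> None:
        self.root.time = t_new
        self.root.bump_epoch()
        self.renormalize_kinetics()
        self.deliver_events(t_new)
        self.scan_conditions(t_new)
        self.root.bump_epoch()

    # -- tree-walk Euler -----------------------------------------------------

    def euler_tree_step(self, t: float, dt: float) -> None:
        updates = self.compute_derivatives()
        for node, var, d in updates:
            node.state[var] += dt * d
        self._check_finite()
        self.finish_step(t + dt)

    def _check_finite(self) -> None:
        for node in self.nodes:
            for var, v in node.state.items():
                if not math.isfinite(v):
                    raise EngineError(
                        f"non-finite state {node.path + '/' + var!r} during integration"
                    )


# --------------------------------------------------------------------------
# Flattened system


class FlatSystem(_Hybrid):
    """Path-prefixed state-vector view of the instance tree.

    The layout is the ordered list of (instance path, state name) pairs;
    derivative evaluation writes the vector back into the tree, so scoped
    requirements bind to their resolved ancestor slots exactly as in the
    tree walk.
    """

    def __init__(self, root: rt.InstanceTreeRoot):
        super().__init__(root)
        self._build_layout()
        self._reject_derived_cycles()

    def _build_layout(self) -> None:
        self.layout: list[tuple[rt.InstanceNode, str]] = []
        for node in self.nodes:
            for var in node.type.dynamics.state_variables:
                self.layout.append((node, var))
        self.names = [f"{n.path}/{v}" if n.path else v for n, v in self.layout]

    def _reject_derived_cycles(self) -> None:
        for node in self.nodes:
            for name in node.type.dynamics.derived_variables:
                try:
                    rt.resolve_value(node, name)
                except rt.RuntimeError_ as exc:
                    if "cycle" in str(exc):
                        raise EngineError(str(exc)) from None
                    raise

    def read_state(self) -> np.ndarray:
        return np.array([n.state[v] for n, v in self.layout], dtype=float)

    def write_state(self, y: np.ndarray) -> None:
        for (n, v), val in zip(self.layout, y):
            n.state[v] = val
        self.root.bump_epoch()

    def derivatives(self, t: float, y: np.ndarray) -> np.ndarray:
        self.write_state(y)
        self.root.time = t
        dydt = np.zeros(len(self.layout))
        index = {(id(n), v): i for i, (n, v) in enumerate(self.layout)}
        for node, var, d in self.compute_derivatives():
            dydt[index[(id(node), var)]] += d
        return dydt

    def step(self, t: float, dt: float, method: str = "rk4") -> None:
        y0 = self.read_state()
        if method == "euler":
            y1 = y0 + dt * self.derivatives(t, y0)
        elif method == "rk4":
            k1 = self.derivatives(t, y0)
            k2 = self.derivatives(t + dt / 2.0, y0 + (dt / 2.0) * k1)
            k3 = self.derivatives(t + dt / 2.0, y0 + (dt / 2.0) * k2)
            k4 = self.derivatives(t + dt, y0 + dt * k3)
            y1 = y0 + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        else:
            raise EngineError(f"unknown method {method!r}")
        if not np.all(np.isfinite(y1)):
            bad = self.names[int(np.argmax(~np.isfinite(y1)))]
            raise EngineError(f"non-finite state {bad!r} during integration")
        self.write_state(y1)
        self.finish_step(t + dt)


def flatten(root: rt.InstanceTreeRoot) -> FlatSystem:
    """Flatten a built instance tree into a state-vector system."""
    return FlatSystem(root)


# --------------------------------------------------------------------------
# Simulation spec and traces


@dataclass
class SimulationSpec:
    target: str  # component id of the model to run
    step: float  # seconds
    length: float  # seconds
    #: sink file name -> ordered record paths; display sinks map to None file
    records: list[str] = field(default_factory=list)
    sinks: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class RecordedTraces:
    times: np.ndarray
    records: dict[str, np.ndarray]
    events: list[tuple[float, str, str]]
    sinks: dict[str, list[str]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def _parse_simulation_component(raw, doc: LemsDocument) -> SimulationSpec:
    step = parse_quantity(raw.attributes["step"], doc.units)
    length = parse_quantity(raw.attributes["length"], doc.units)
    for q, what in ((step, "step"), (length, "length")):
        if q.dimension != TIME:
            raise EngineError(f"Simulation {what} must be a time")
    if step.magnitude <= 0 or length.magnitude < 0:
        raise EngineError("Simulation needs step > 0 and length >= 0")
    spec = SimulationSpec(
        target=raw.attributes["target"], step=step.magnitude, length=length.magnitude
    )
    for child in raw.children:
        if child.type_name == "Display":
            for line in child.children:
                q = line.attributes.get("quantity")
                if q and q not in spec.records:
                    spec.records.append(q)
        elif child.type_name == "OutputFile":
            fname = child.attributes.get("fileName", f"{child.id}.tsv")
            cols = [
                c.attributes["quantity"]
                for c in child.children
                if c.type_name == "OutputColumn"
            ]
            spec.sinks[fname] = cols
            for q in cols:
                if q not in spec.records:
                    spec.records.append(q)
        elif child.type_name == "EventOutputFile":
            pass  # the event log is always recorded
    return spec


def _record_getter(root: rt.InstanceTreeRoot, path: str):
    segs = path.split("/")
    if segs and segs[0] == root.component.id:
        segs = segs[1:]
    if not segs:
        raise EngineError(f"record path {path!r} names no quantity")
    *prefix, leaf = segs
    try:
        node = root.find("/".join(prefix)) if prefix else root
    except rt.RuntimeError_ as exc:
        raise EngineError(f"record path {path!r}: {exc}") from None

    def get() -> float:
        if leaf in node.state:
            return node.state[leaf]
        try:
            return rt.exposure_value(node, leaf)
        except rt.RuntimeError_:
            return rt.resolve_value(node, leaf)

    try:
        get()
    except rt.RuntimeError_ as exc:
        raise EngineError(f"record path {path!r} does not resolve: {exc}") from None
    return get


def simulate(
    doc: LemsDocument,
    target: str | None = None,
    seed: int | None = None,
    method: str | None = None,
    dt: float | None = None,
    length: float | None = None,
    records: list[str] | None = None,
    validate: bool = True,
) -> RecordedTraces:
    """Run the document's Target to completion and record traces.

    The Target (or ``target``) names either a Simulation component carrying
    step/length/records, or a model component directly, in which case
    ``dt`` and ``length`` overrides are required.  Runs are deterministic
    given (document, seed, method, dt).
    """
    if validate:
        report = check_document(doc)
        if report:
            raise SemanticError("; ".join(report))

    target = target or (doc.targets[0] if doc.targets else None)
    if target is None:
        raise EngineError("no Target in document and no target override")
    raw = doc.component_by_id(target)
    if raw is None:
        raise EngineError(f"target component {target!r} not found")

    if raw.type_name == "Simulation":
        spec = _parse_simulation_component(raw, doc)
    else:
        if dt is None or length is None:
            raise EngineError(
                "target is not a Simulation component; dt and length overrides required"
            )
        spec = SimulationSpec(target=target, step=dt, length=length)
    if dt is not None:
        spec.step = dt
    if length is not None:
        spec.length = length
    if records:
        spec.records = list(records)
    method = method or "rk4"

    rng = np.random.default_rng(0 if seed is None else seed)
    root = rt.build_instance_tree(doc, spec.target, rng=rng)
    system = FlatSystem(root)
    system.prime_conditions()

    getters = {path: _record_getter(root, path) for path in spec.records}
    n_steps = int(round(spec.length / spec.step))
    times = np.arange(n_steps + 1) * spec.step
    series = {path: np.empty(n_steps + 1) for path in spec.records}

    root.time = 0.0
    for path, get in getters.items():
        series[path][0] = get()
    for i in range(n_steps):
        t = i * spec.step
        if method == "euler-tree":
            system.euler_tree_step(t, spec.step)
        else:
            system.step(t, spec.step, method)
        for path, get in getters.items():
            series[path][i + 1] = get()

    return RecordedTraces(
        times=times,
        records=series,
        events=list(root.event_log),
        sinks=dict(spec.sinks),
        meta={"seed": seed, "method": method, "dt": spec.step, "length": spec.length},
    )


# --------------------------------------------------------------------------
# Output


def _fmt(x: float) -> str:
    return repr(float(x))


def write_traces(traces: RecordedTraces, outdir: str) -> list[str]:
    """Write one TSV per output sink (column 1 = time in seconds, SI values,
    full float precision) plus the event log; returns the paths written."""
    os.makedirs(outdir, exist_ok=True)
    written: list[str] = []
    sinks = traces.sinks or {"traces.tsv": list(traces.records)}
    for fname, cols in sinks.items():
        path = os.path.join(outdir, os.path.basename(fname))
        with open(path, "w") as fh:
            fh.write("time\t" + "\t".join(cols) + "\n")
            for i, t in enumerate(traces.times):
                row = [_fmt(t)] + [_fmt(traces.records[c][i]) for c in cols]
                fh.write("\t".join(row) + "\n")
        written.append(path)
    epath = os.path.join(outdir, "events.tsv")
    with open(epath, "w") as fh:
        fh.write("time\tpath\tport\n")
        for t, who, port in traces.events:
            fh.write(f"{_fmt(t)}\t{who}\t{port}\n")
    written.append(epath)
    return written
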