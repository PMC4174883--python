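"""Instance trees, scoped value access and the event queue.

Building a model turns the validated component tree into an instance tree:
each component yields one instance node carrying its own state variables,
``MultiInstantiate`` directives expand populations into independent sibling
instances, and ``EventConnection`` directives wire spike routes (optionally
instantiating a receiver synapse onto the target's attachment slot, one per
connection).

Scoped access follows containment: a symbol resolves locally first
(parameter, state, derived value), and a declared Requirement searches the
ancestor chain nearest-first for an exposure of that name — so a gate deep
inside a channel reads the membrane potential of the cell it sits on and of
no other cell.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

from . import expressions as ex
from .document import LemsDocument
from .semantics import (
    ChildInstance,
    DerivedVariable,
    EventConnection,
    MultiInstantiate,
    SemanticError,
    TypedComponent,
    check_component,
    resolve_type,
)
from .units import TIME, UnitError, parse_quantity

__all__ = [
    "InstanceNode",
    "EventQueue",
    "build_instance_tree",
    "resolve_value",
    "connect_event",
    "deliver_due_events",
    "RuntimeError_",
]


class RuntimeError_(ValueError):
    """Instantiation or value-resolution failure."""


@dataclass
class Connection:
    target: "InstanceNode"
    port: str
    delay: float  # seconds
    weight: float


class InstanceNode:
    """One runtime instance of a component, with independent state."""

    __slots__ = (
        "name", "parent", "component", "type", "state", "regime",
        "children", "attachments", "out_connections", "in_forward",
        "_values", "_dv_cache", "_compiled", "root",
    )

    def __init__(self, name: str, component: TypedComponent, parent: "InstanceNode | None"):
        self.name = name
        self.parent = parent
        self.component = component
        self.type = component.type
        self.state: dict[str, float] = {}
        self.regime: str | None = None
        self.children: dict[str, "InstanceNode | list[InstanceNode]"] = {}
        self.attachments: dict[str, list[InstanceNode]] = {
            slot: [] for slot in component.type.attachments
        }
        # out-port (or forwarded in-port) -> connections
        self.out_connections: dict[str, list[Connection]] = {}
        self.in_forward: dict[str, list[Connection]] = {}
        self._values: dict[str, float] = {}  # params, derived params, constants (SI)
        self._dv_cache: dict[str, tuple[int, float]] = {}
        self._compiled: dict[int, tuple] = {}
        self.root: "InstanceTreeRoot | None" = None

    # -- structure ---------------------------------------------------------

    @property
    def path(self) -> str:
        parts = []
        node: InstanceNode | None = self
        while node is not None and node.parent is not None:
            parts.append(node.name)
            node = node.parent
        return "/".join(reversed(parts))

    def iter_nodes(self):
        yield self
        for child in self.children.values():
            if isinstance(child, list):
                for c in child:
                    yield from c.iter_nodes()
            else:
                yield from child.iter_nodes()
        for coll in self.attachments.values():
            for c in coll:
                yield from c.iter_nodes()

    def child_collection(self, name: str) -> list["InstanceNode"]:
        """Children of a slot or attachment collection, in creation order."""
        if name in self.attachments:
            return self.attachments[name]
        got = self.children.get(name)
        if got is None:
            return []
        return got if isinstance(got, list) else [got]

    def find(self, path: str) -> "InstanceNode":
        """Resolve a slash-separated instance path relative to this node."""
        node: InstanceNode = self
        for seg in path.split("/"):
            if not seg:
                continue
            if seg == "parent" or seg == "..":
                if node.parent is None:
                    raise RuntimeError_(f"path {path!r}: no parent above {node.path!r}")
                node = node.parent
                continue
            if seg == "this" or seg == ".":
                continue
            nxt = _child_by_name(node, seg)
            if nxt is None:
                raise RuntimeError_(
                    f"path {path!r}: no child {seg!r} under {node.path or '<root>'!r}"
                )
            node = nxt
        return node


def _child_by_name(node: InstanceNode, seg: str) -> InstanceNode | None:
    got = node.children.get(seg)
    if isinstance(got, InstanceNode):
        return got
    if "[" in seg and seg.endswith("]"):
        base, idx = seg[:-1].split("[", 1)
        k = int(idx)
        for coll in (node.children, node.attachments):
            got = coll.get(base)
            if isinstance(got, list) and 0 <= k < len(got):
                return got[k]
        # population members are stored flat under their indexed name
        got = node.children.get(seg)
        if isinstance(got, InstanceNode):
            return got
    # search list-valued slots for a member with this instance name
    for got in node.children.values():
        if isinstance(got, list):
            for c in got:
                if c.name == seg:
                    return c
    return None


class InstanceTreeRoot(InstanceNode):
    """Root node; also carries the evaluation epoch and event log."""

    __slots__ = ("epoch", "event_log", "queue", "rng", "time")

    def __init__(self, component: TypedComponent):
        super().__init__(component.id, component, None)
        self.epoch = 0
        self.event_log: list[tuple[float, str, str]] = []
        self.queue = EventQueue()
        self.rng = None
        self.time = 0.0

    def bump_epoch(self) -> None:
        self.epoch += 1


# --------------------------------------------------------------------------
# Event queue


class EventQueue:
    """Pending events ordered by (delivery time, insertion sequence)."""

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, InstanceNode, str, float]] = []
        self._seq = itertools.count()

    def push(self, when: float, target: InstanceNode, port: str, weight: float) -> None:
        heapq.heappush(self._heap, (when, next(self._seq), target, port, weight))

    def __len__(self) -> int:
        return len(self._heap)

    def peek_time(self) -> float | None:
        return self._heap[0][0] if self._heap else None

    def pop_due(self, now: float):
        """Remove and return all events with delivery time <= now, FIFO
        within equal times."""
        out = []
        while self._heap and self._heap[0][0] <= now:
            when, _, target, port, weight = heapq.heappop(self._heap)
            out.append((target, port, weight))
        return out


def deliver_due_events(queue: EventQueue, now: float):
    """Drain all events due at or before ``now`` (queue contract helper)."""
    return queue.pop_due(now)


# --------------------------------------------------------------------------
# Building


def build_instance_tree(doc: LemsDocument, target_id: str, rng=None) -> InstanceTreeRoot:
    """Instantiate the component named ``target_id`` into a runtime tree.

    State variables start at 0 (kinetic-scheme occupancies: first state 1),
    then OnStart assignments run in pre-order document order, then each
    multi-regime instance enters its initial regime and runs its OnEntry.
    """
    raw = doc.component_by_id(target_id)
    if raw is None:
        raise RuntimeError_(f"no top-level component with id {target_id!r}")
    tc = check_component(raw, doc)
    root = InstanceTreeRoot(tc)
    root.rng = rng
    pending: list[tuple[InstanceNode, EventConnection]] = []
    _populate(root, doc, pending)
    for node, directive in pending:
        _apply_event_connection(node, directive, doc)
    _initialize(root)
    return root


def _instantiate(name: str, tc: TypedComponent, parent: InstanceNode,
                 doc: LemsDocument, pending) -> InstanceNode:
    node = InstanceNode(name, tc, parent)
    node.root = parent.root
    _populate(node, doc, pending)
    return node


def _populate(node: InstanceNode, doc: LemsDocument, pending) -> None:
    if node.root is None and isinstance(node, InstanceTreeRoot):
        node.root = node
    tc = node.component
    # bind parameter/constant values in SI
    for pname, q in tc.parameters.items():
        node._values[pname] = q.magnitude
    for cname, q in tc.type.constants.items():
        node._values[cname] = q.magnitude
    for cname, c in doc.constants.items():
        node._values.setdefault(cname, c.quantity.magnitude)
    # derived parameters: functions of parameters/constants, fixed at build
    for dpname, (dim, expr) in tc.type.derived_parameters.items():
        node._values[dpname] = ex.eval_expression(expr, node._values)

    for slot, kids in tc.children.items():
        single = tc.type.child_slots[slot].single
        if single:
            node.children[slot] = _instantiate(slot, kids[0], node, doc, pending)
        else:
            node.children[slot] = [
                _instantiate(kid.id, kid, node, doc, pending) for kid in kids
            ]

    for name in tc.type.dynamics.state_variables:
        node.state[name] = 0.0
    _init_kinetic_occupancies(node)

    for directive in tc.type.structure:
        if isinstance(directive, MultiInstantiate):
            _apply_multi_instantiate(node, directive, doc, pending)
        elif isinstance(directive, ChildInstance):
            _apply_child_instance(node, directive, doc, pending)
        elif isinstance(directive, EventConnection):
            pending.append((node, directive))


def _init_kinetic_occupancies(node: InstanceNode) -> None:
    for scheme in node.type.dynamics.kinetic_schemes:
        states = node.child_collection(scheme.nodes)
        for k, st in enumerate(states):
            st.state[scheme.state_variable] = 1.0 if k == 0 else 0.0


def _referenced_component(node: InstanceNode, ref_name: str, doc: LemsDocument) -> TypedComponent:
    cid = node.component.refs.get(ref_name)
    if cid is None:
        raise RuntimeError_(
            f"{node.path or node.name}: no component reference {ref_name!r}"
        )
    raw = doc.component_by_id(cid)
    if raw is None:
        raise RuntimeError_(
            f"{node.path or node.name}: reference {ref_name!r} names missing component {cid!r}"
        )
    return check_component(raw, doc)


def _apply_multi_instantiate(node, directive: MultiInstantiate, doc, pending) -> None:
    count_q = node.component.parameters.get(directive.number)
    if count_q is None:
        raise RuntimeError_(
            f"{node.path or node.name}: MultiInstantiate count parameter "
            f"{directive.number!r} not set"
        )
    count = count_q.magnitude
    if count < 0 or count != int(count):
        raise RuntimeError_(
            f"{node.path or node.name}: population count must be a non-negative "
            f"integer, got {count!r}"
        )
    tc = _referenced_component(node, directive.component, doc)
    members = [
        _instantiate(f"{tc.id}[{k}]", tc, node, doc, pending)
        for k in range(int(count))
    ]
    node.children[tc.id] = members


def _apply_child_instance(node, directive: ChildInstance, doc, pending) -> None:
    tc = _referenced_component(node, directive.component, doc)
    node.children[directive.component] = _instantiate(directive.component, tc, node, doc, pending)


def _resolve_endpoint(node: InstanceNode, spec: str) -> InstanceNode:
    """Resolve an EventConnection endpoint.

    ``spec`` names a Text field of the declaring component when one exists
    (its value is the path); otherwise it is itself the path.  Paths are
    resolved relative to the declaring node, then its parent.
    """
    path = node.component.texts.get(spec, spec)
    for base in (node, node.parent):
        if base is None:
            continue
        try:
            return base.find(path)
        except RuntimeError_:
            continue
    raise RuntimeError_(
        f"{node.path or node.name}: cannot resolve event endpoint {path!r}"
    )


def _scalar_attr(node: InstanceNode, spec: str | None, doc: LemsDocument,
                 default: float, want_time: bool) -> float:
    if spec is None:
        return default
    q = node.component.parameters.get(spec)
    if q is None:
        try:
            q = parse_quantity(spec, doc.units)
        except UnitError:
            raise RuntimeError_(
                f"{node.path or node.name}: cannot interpret {spec!r} as a "
                f"parameter name or quantity"
            ) from None
    if want_time and q.dimension != TIME and not q.dimension.is_dimensionless:
        raise RuntimeError_(f"{node.path or node.name}: delay {spec!r} is not a time")
    return q.magnitude


def _apply_event_connection(node: InstanceNode, d: EventConnection, doc: LemsDocument) -> None:
    source = _resolve_endpoint(node, d.from_)
    target = _resolve_endpoint(node, d.to)
    delay = _scalar_attr(node, d.delay, doc, 0.0, want_time=True)
    weight = _scalar_attr(node, d.weight, doc, 1.0, want_time=False)
    receiver = None
    if d.receiver is not None:
        receiver = _referenced_component(node, d.receiver, doc)
    connect_event(source, d.source_port, target, d.target_port, delay, weight,
                  receiver=receiver, receiver_container=d.receiver_container, doc=doc)


def connect_event(source: InstanceNode, source_port: str | None,
                  target: InstanceNode, target_port: str | None,
                  delay: float = 0.0, weight: float = 1.0,
                  receiver: TypedComponent | None = None,
                  receiver_container: str | None = None,
                  doc: LemsDocument | None = None) -> None:
    """Wire a spike route from a source port to a target's in-port.

    If a receiver component is given it is instantiated onto the target's
    attachment slot (named ``slot[k]`` in creation order) and becomes the
    actual event target.  A source port may be an *in* port, in which case
    events received on it are forwarded (the parent-to-child relay pattern).
    """
    sport = source_port or _single_port(source, "out")
    if receiver is not None:
        slot = receiver_container or _attachment_slot_for(target, receiver)
        if slot not in target.attachments:
            raise RuntimeError_(
                f"{target.path!r} has no attachment slot {slot!r}"
            )
        declared = target.type.attachments[slot]
        if not receiver.type.is_subtype_of(declared):
            raise RuntimeError_(
                f"receiver type {receiver.type.name!r} does not extend the "
                f"attachment type {declared!r} of slot {slot!r}"
            )
        pending: list = []
        k = len(target.attachments[slot])
        inst = _instantiate(f"{slot}[{k}]", receiver, target, doc, pending)
        target.attachments[slot].append(inst)
        for n, directive in pending:
            _apply_event_connection(n, directive, doc)
        _initialize(inst, toplevel=False)
        target = inst

    tport = target_port or _single_port(target, "in")
    sdir = source.type.event_ports.get(sport)
    tdir = target.type.event_ports.get(tport)
    if tdir != "in":
        raise RuntimeError_(
            f"target port {tport!r} on {target.path!r} is not an in-port"
        )
    conn = Connection(target, tport, delay, weight)
    if sdir == "out":
        source.out_connections.setdefault(sport, []).append(conn)
    elif sdir == "in":
        source.in_forward.setdefault(sport, []).append(conn)
    else:
        raise RuntimeError_(
            f"source port {sport!r} on {source.path!r} is not declared"
        )


def _single_port(node: InstanceNode, direction: str) -> str:
    ports = [p for p, d in node.type.event_ports.items() if d == direction]
    if len(ports) != 1:
        raise RuntimeError_(
            f"{node.path!r}: cannot infer {direction}-port (candidates: {ports})"
        )
    return ports[0]


def _attachment_slot_for(target: InstanceNode, receiver: TypedComponent) -> str:
    for slot, tname in target.type.attachments.items():
        if receiver.type.is_subtype_of(tname):
            return slot
    raise RuntimeError_(
        f"{target.path!r} has no attachment slot accepting {receiver.type.name!r}"
    )


# --------------------------------------------------------------------------
# Initialization


def _initialize(root: InstanceNode, toplevel: bool = True) -> None:
    """OnStart assignments in pre-order, then initial-regime entry."""
    nodes = list(root.iter_nodes())
    for node in nodes:
        for assign in node.type.dynamics.on_start:
            node.state[assign.variable] = _eval_at(node, assign.expr)
            node.root.bump_epoch()
    for node in nodes:
        regimes = node.type.dynamics.regimes
        if regimes:
            initial = [r for r in regimes.values() if r.initial]
            if len(initial) != 1:
                raise RuntimeError_(
                    f"{node.path!r}: needs exactly one initial regime"
                )
            node.regime = initial[0].name
            for assign in initial[0].on_entry:
                node.state[assign.variable] = _eval_at(node, assign.expr)
            node.root.bump_epoch()


# --------------------------------------------------------------------------
# Value resolution


def _eval_at(node: InstanceNode, expr: ex.Node, extra: dict | None = None) -> float:
    syms = ex.free_symbols(expr)
    bindings = {}
    for s in syms:
        if extra is not None and s in extra:
            bindings[s] = extra[s]
        else:
            bindings[s] = resolve_value(node, s)
    return ex.eval_expression(expr, bindings, node.root.rng if node.root else None)


def resolve_value(node: InstanceNode, symbol: str, _stack: tuple = ()) -> float:
    """Resolve a symbol in a node's scope.

    Order: simulation time ``t``; local state; local parameter / derived
    parameter / constant; local derived variable; then, for a declared
    Requirement, the nearest ancestor exposing that name.
    """
    if symbol == "t":
        return node.root.time if node.root else 0.0
    if symbol in node.state:
        return node.state[symbol]
    if symbol in node._values:
        return node._values[symbol]
    dv = node.type.dynamics.derived_variables.get(symbol)
    if dv is not None:
        return _derived_value(node, dv, _stack)
    if symbol in node.type.requirements:
        anc = node.parent
        while anc is not None:
            if symbol in anc.type.exposures:
                return exposure_value(anc, symbol, _stack)
            anc = anc.parent
        raise RuntimeError_(
            f"unresolved requirement {symbol!r} at {node.path or '<root>'!r}"
        )
    raise RuntimeError_(f"unresolved symbol {symbol!r} at {node.path or '<root>'!r}")


def exposure_value(node: InstanceNode, exposure: str, _stack: tuple = ()) -> float:
    """Current value a node publishes under an exposure name."""
    dyn = node.type.dynamics
    for state, exp_name in dyn.state_exposures.items():
        if exp_name == exposure:
            return node.state[state]
    dv = dyn.derived_variables.get(exposure)
    if dv is None:
        for dv2 in dyn.derived_variables.values():
            if dv2.exposure == exposure:
                dv = dv2
                break
    if dv is not None:
        return _derived_value(node, dv, _stack)
    if exposure in node.state:
        return node.state[exposure]
    if exposure in node._values:
        return node._values[exposure]
    raise RuntimeError_(
        f"exposure {exposure!r} has no value at {node.path or '<root>'!r}"
    )


def _derived_value(node: InstanceNode, dv: DerivedVariable, _stack: tuple) -> float:
    root = node.root
    key = dv.name
    if root is not None:
        hit = node._dv_cache.get(key)
        if hit is not None and hit[0] == root.epoch:
            return hit[1]
    token = (id(node), key)
    if token in _stack:
        raise RuntimeError_(
            f"derived-variable cycle at {node.path!r}:{key} "
            f"(chain length {len(_stack)})"
        )
    stack = _stack + (token,)
    if dv.select is not None:
        value = _select_value(node, dv, stack)
    else:
        fn, syms = ex.cached_compile(dv.expr)
        bindings = {s: resolve_value(node, s, stack) for s in syms}
        value = fn(bindings, root.rng if root else None)
    if root is not None:
        node._dv_cache[key] = (root.epoch, value)
    return value


def _select_value(node: InstanceNode, dv: DerivedVariable, stack: tuple) -> float:
    """Evaluate a selection path, e.g. ``synapses[*]/i`` with reduce."""
    parts = dv.select.split("/")
    *collection_parts, leaf = parts
    targets: list[InstanceNode] = [node]
    for seg in collection_parts:
        nxt: list[InstanceNode] = []
        for cur in targets:
            if seg.endswith("[*]"):
                nxt.extend(cur.child_collection(seg[:-3]))
            else:
                found = _child_by_name(cur, seg)
                if found is None:
                    raise RuntimeError_(
                        f"{node.path!r}: select {dv.select!r}: no child {seg!r}"
                    )
                nxt.append(found)
        targets = nxt
    values = [exposure_value(t, leaf, stack) for t in targets]
    if dv.reduce == "multiply":
        out = 1.0
        for v in values:
            out *= v
        return out
    if dv.reduce == "add" or dv.reduce is None and len(values) != 1:
        return float(sum(values))
    if dv.reduce is None:
        return values[0]
    raise RuntimeError_(f"unknown reduce {dv.reduce!r} in select {dv.select!r}")
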