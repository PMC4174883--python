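"""Component-type resolution, component validation and dynamics checking.

A ComponentType may extend another, inheriting its parameters, exposures,
requirements, ports, child slots, structure and dynamics.  A derived type
may add members and may override an inherited DerivedVariable or
TimeDerivative by redeclaring the same name; parameters and exposures may
never change dimension.  A component of type T fills any child slot whose
declared type is T or an ancestor of T.

Dimension checking of Dynamics verifies that every TimeDerivative has
dimension dim(state)/time, every DerivedVariable and StateAssignment
matches its declared target dimension, and every condition compares like
dimensions.  Violations are collected into a report rather than raising at
the first problem; a non-empty report blocks simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lxml import etree

from . import expressions as ex
from .document import DocumentError, LemsDocument, RawComponent, RawComponentType
from .units import DIMENSIONLESS, TIME, Dimension, Quantity, UnitError, dim_combine, parse_quantity

__all__ = [
    "ResolvedComponentType",
    "TypedComponent",
    "Dynamics",
    "Regime",
    "KineticScheme",
    "DerivedVariable",
    "StateAssign",
    "EventOut",
    "Transition",
    "ConditionHandler",
    "EventHandler",
    "ChildSpec",
    "StructureDirective",
    "MultiInstantiate",
    "ChildInstance",
    "EventConnection",
    "resolve_type",
    "check_component",
    "check_dynamics",
    "check_document",
    "SemanticError",
]


class SemanticError(ValueError):
    """Type-resolution or component-validation failure."""


# --------------------------------------------------------------------------
# Dynamics data model


@dataclass
class DerivedVariable:
    """Either an expression over local scope or a selection over a child
    collection with an ``add``/``multiply`` reduction (empty collections
    reduce to the identity: 0 for add, 1 for multiply)."""

    name: str
    dimension: Dimension
    exposure: str | None = None
    expr: ex.Node | None = None
    select: str | None = None
    reduce: str | None = None  # "add" | "multiply"


@dataclass
class StateAssign:
    variable: str
    expr: ex.Node


@dataclass
class EventOut:
    port: str


@dataclass
class Transition:
    regime: str


Action = StateAssign | EventOut | Transition


@dataclass
class ConditionHandler:
    test: ex.Node
    actions: list[Action]


@dataclass
class EventHandler:
    port: str
    actions: list[Action]


@dataclass
class KineticScheme:
    """Mean-field occupancy dynamics over a small state graph.

    ``nodes``/``edges`` name child collections; each edge component names
    its endpoints through the ``edge_source``/``edge_target`` text fields
    and exposes forward/reverse rates under the given exposure names.
    Occupancies live in the ``state_variable`` state of each node child.
    """

    name: str
    nodes: str
    state_variable: str
    edges: str
    edge_source: str
    edge_target: str
    forward_rate: str
    reverse_rate: str


@dataclass
class Regime:
    name: str
    initial: bool = False
    time_derivatives: dict[str, ex.Node] = field(default_factory=dict)
    on_entry: list[StateAssign] = field(default_factory=list)
    on_conditions: list[ConditionHandler] = field(default_factory=list)
    on_events: list[EventHandler] = field(default_factory=list)


@dataclass
class Dynamics:
    state_variables: dict[str, Dimension] = field(default_factory=dict)
    #: state variable name -> exposure name it publishes under (if any)
    state_exposures: dict[str, str] = field(default_factory=dict)
    derived_variables: dict[str, DerivedVariable] = field(default_factory=dict)
    time_derivatives: dict[str, ex.Node] = field(default_factory=dict)
    on_start: list[StateAssign] = field(default_factory=list)
    on_events: list[EventHandler] = field(default_factory=list)
    on_conditions: list[ConditionHandler] = field(default_factory=list)
    regimes: dict[str, Regime] = field(default_factory=dict)
    kinetic_schemes: list[KineticScheme] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not (
            self.state_variables
            or self.derived_variables
            or self.regimes
            or self.kinetic_schemes
        )


# --------------------------------------------------------------------------
# Structure data model


@dataclass
class MultiInstantiate:
    number: str  # parameter name holding the count
    component: str  # component-reference name


@dataclass
class ChildInstance:
    component: str  # component-reference name


@dataclass
class EventConnection:
    """Attribute values name Text/Parameter fields of the declaring
    component where such fields exist, else they are taken literally
    (paths support ``parent`` and ``this`` tokens)."""

    from_: str
    to: str
    source_port: str | None = None
    target_port: str | None = None
    delay: str | None = None
    weight: str | None = None
    receiver: str | None = None  # component-reference name
    receiver_container: str | None = None  # attachment slot on the target


StructureDirective = MultiInstantiate | ChildInstance | EventConnection


@dataclass
class ChildSpec:
    name: str
    type_name: str
    single: bool  # Child (exactly one) vs Children (zero or more)


@dataclass
class ResolvedComponentType:
    """The merged inheritance view of a ComponentType."""

    name: str
    lineage: list[str] = field(default_factory=list)  # self first, root last
    parameters: dict[str, Dimension] = field(default_factory=dict)
    derived_parameters: dict[str, tuple[Dimension, ex.Node]] = field(default_factory=dict)
    constants: dict[str, Quantity] = field(default_factory=dict)
    texts: set[str] = field(default_factory=set)
    exposures: dict[str, Dimension] = field(default_factory=dict)
    requirements: dict[str, Dimension] = field(default_factory=dict)
    child_slots: dict[str, ChildSpec] = field(default_factory=dict)
    component_refs: dict[str, str] = field(default_factory=dict)
    attachments: dict[str, str] = field(default_factory=dict)
    event_ports: dict[str, str] = field(default_factory=dict)  # name -> in|out
    dynamics: Dynamics = field(default_factory=Dynamics)
    structure: list[StructureDirective] = field(default_factory=list)

    def is_subtype_of(self, base: str) -> bool:
        return base in self.lineage


@dataclass
class TypedComponent:
    """A validated component: SI parameter values bound to a resolved type."""

    id: str
    type: ResolvedComponentType
    parameters: dict[str, Quantity] = field(default_factory=dict)
    texts: dict[str, str] = field(default_factory=dict)
    refs: dict[str, str] = field(default_factory=dict)  # ref name -> component id
    children: dict[str, list["TypedComponent"]] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Type resolution


def _local(el) -> str:
    return etree.QName(el).localname


def resolve_type(
    name: str,
    doc: LemsDocument,
    _cache: dict[str, ResolvedComponentType] | None = None,
    _stack: tuple[str, ...] = (),
) -> ResolvedComponentType:
    """Merge a type with its extension chain into a single resolved view."""
    cache = doc.__dict__.setdefault("_resolved_types", {}) if _cache is None else _cache
    if name in cache:
        return cache[name]
    if name in _stack:
        raise SemanticError(
            "cyclic ComponentType extension: " + " -> ".join(_stack + (name,))
        )
    decl = doc.component_types.get(name)
    if decl is None:
        raise SemanticError(f"unknown ComponentType {name!r}")

    if decl.extends is not None:
        base = resolve_type(decl.extends, doc, cache, _stack + (name,))
        rt = _copy_resolved(base)
        rt.name = name
        rt.lineage = [name] + base.lineage
    else:
        rt = ResolvedComponentType(name=name, lineage=[name])

    _merge_declaration(rt, decl, doc)
    cache[name] = rt
    return rt


def _copy_resolved(base: ResolvedComponentType) -> ResolvedComponentType:
    dyn = base.dynamics
    return ResolvedComponentType(
        name=base.name,
        lineage=list(base.lineage),
        parameters=dict(base.parameters),
        derived_parameters=dict(base.derived_parameters),
        constants=dict(base.constants),
        texts=set(base.texts),
        exposures=dict(base.exposures),
        requirements=dict(base.requirements),
        child_slots=dict(base.child_slots),
        component_refs=dict(base.component_refs),
        attachments=dict(base.attachments),
        event_ports=dict(base.event_ports),
        dynamics=Dynamics(
            state_variables=dict(dyn.state_variables),
            state_exposures=dict(dyn.state_exposures),
            derived_variables=dict(dyn.derived_variables),
            time_derivatives=dict(dyn.time_derivatives),
            on_start=list(dyn.on_start),
            on_events=list(dyn.on_events),
            on_conditions=list(dyn.on_conditions),
            regimes=dict(dyn.regimes),
            kinetic_schemes=list(dyn.kinetic_schemes),
        ),
        structure=list(base.structure),
    )


def _dim(doc: LemsDocument, name: str | None, context: str) -> Dimension:
    if name is None or name == "none":
        return DIMENSIONLESS
    d = doc.dimensions.get(name)
    if d is None:
        raise SemanticError(f"{context}: unknown dimension {name!r}")
    return d


def _merge_declaration(rt: ResolvedComponentType, decl: RawComponentType, doc: LemsDocument) -> None:
    el = decl.element
    ctx = f"ComponentType {decl.name!r}"
    for sub in el:
        if not isinstance(sub.tag, str):
            continue
        kind = _local(sub)
        if kind == "Parameter":
            _add_member(rt.parameters, sub.get("name"), _dim(doc, sub.get("dimension"), ctx), ctx, "parameter")
        elif kind == "DerivedParameter":
            name = sub.get("name")
            dim = _dim(doc, sub.get("dimension"), ctx)
            expr = ex.parse_expression(sub.get("value"))
            rt.derived_parameters[name] = (dim, expr)
        elif kind == "Constant":
            name = sub.get("name")
            q = parse_quantity(sub.get("value"), doc.units)
            rt.constants[name] = q
        elif kind == "Text":
            rt.texts.add(sub.get("name"))
        elif kind == "Exposure":
            _add_member(rt.exposures, sub.get("name"), _dim(doc, sub.get("dimension"), ctx), ctx, "exposure")
        elif kind == "Requirement":
            _add_member(rt.requirements, sub.get("name"), _dim(doc, sub.get("dimension"), ctx), ctx, "requirement")
        elif kind == "Child":
            name = sub.get("name")
            rt.child_slots[name] = ChildSpec(name, sub.get("type"), single=True)
        elif kind == "Children":
            name = sub.get("name")
            rt.child_slots[name] = ChildSpec(name, sub.get("type"), single=False)
        elif kind == "ComponentReference":
            rt.component_refs[sub.get("name")] = sub.get("type")
        elif kind in ("Attachments", "Attachment"):
            rt.attachments[sub.get("name")] = sub.get("type")
        elif kind == "EventPort":
            rt.event_ports[sub.get("name")] = sub.get("direction", "in")
        elif kind == "Dynamics":
            _merge_dynamics(rt.dynamics, sub, doc, ctx)
        elif kind == "Structure":
            rt.structure.extend(_parse_structure(sub, ctx))
        elif kind == "Simulation":
            pass  # display/record capabilities; handled by the engine
        else:
            raise SemanticError(f"{ctx}: unknown sub-element {kind!r}")


def _add_member(target: dict, name: str | None, dim: Dimension, ctx: str, kind: str) -> None:
    if name is None:
        raise SemanticError(f"{ctx}: {kind} without a name")
    if name in target and target[name] != dim:
        raise SemanticError(
            f"{ctx}: {kind} {name!r} redeclared with conflicting dimension "
            f"({target[name].describe()} vs {dim.describe()})"
        )
    target[name] = dim


def _parse_actions(el, ctx: str) -> list[Action]:
    actions: list[Action] = []
    for sub in el:
        if not isinstance(sub.tag, str):
            continue
        kind = _local(sub)
        if kind == "StateAssignment":
            actions.append(
                StateAssign(sub.get("variable"), ex.parse_expression(sub.get("value")))
            )
        elif kind == "EventOut":
            actions.append(EventOut(sub.get("port")))
        elif kind == "Transition":
            actions.append(Transition(sub.get("regime")))
        else:
            raise SemanticError(f"{ctx}: unknown action element {kind!r}")
    return actions


def _merge_dynamics(dyn: Dynamics, el, doc: LemsDocument, ctx: str) -> None:
    for sub in el:
        if not isinstance(sub.tag, str):
            continue
        kind = _local(sub)
        if kind == "StateVariable":
            name = sub.get("name")
            _add_member(dyn.state_variables, name, _dim(doc, sub.get("dimension"), ctx), ctx, "state variable")
            if sub.get("exposure"):
                dyn.state_exposures[name] = sub.get("exposure")
        elif kind == "DerivedVariable":
            name = sub.get("name")
            value = sub.get("value")
            dv = DerivedVariable(
                name=name,
                dimension=_dim(doc, sub.get("dimension"), ctx),
                exposure=sub.get("exposure"),
                expr=ex.parse_expression(value) if value else None,
                select=sub.get("select"),
                reduce=sub.get("reduce"),
            )
            if dv.expr is None and dv.select is None:
                raise SemanticError(f"{ctx}: DerivedVariable {name!r} has neither value nor select")
            dyn.derived_variables[name] = dv  # override-by-name is legal
        elif kind == "TimeDerivative":
            dyn.time_derivatives[sub.get("variable")] = ex.parse_expression(sub.get("value"))
        elif kind == "OnStart":
            dyn.on_start.extend(
                a for a in _parse_actions(sub, ctx) if isinstance(a, StateAssign)
            )
        elif kind == "OnEvent":
            dyn.on_events.append(EventHandler(sub.get("port"), _parse_actions(sub, ctx)))
        elif kind == "OnCondition":
            dyn.on_conditions.append(
                ConditionHandler(
                    ex.parse_expression(sub.get("test"), boolean=True),
                    _parse_actions(sub, ctx),
                )
            )
        elif kind == "Regime":
            regime = Regime(sub.get("name"), initial=sub.get("initial", "false") == "true")
            for r in sub:
                if not isinstance(r.tag, str):
                    continue
                rkind = _local(r)
                if rkind == "TimeDerivative":
                    regime.time_derivatives[r.get("variable")] = ex.parse_expression(r.get("value"))
                elif rkind == "OnEntry":
                    regime.on_entry.extend(
                        a for a in _parse_actions(r, ctx) if isinstance(a, StateAssign)
                    )
                elif rkind == "OnCondition":
                    regime.on_conditions.append(
                        ConditionHandler(
                            ex.parse_expression(r.get("test"), boolean=True),
                            _parse_actions(r, ctx),
                        )
                    )
                elif rkind == "OnEvent":
                    regime.on_events.append(EventHandler(r.get("port"), _parse_actions(r, ctx)))
                else:
                    raise SemanticError(f"{ctx}: unknown Regime sub-element {rkind!r}")
            dyn.regimes[regime.name] = regime
        elif kind == "KineticScheme":
            dyn.kinetic_schemes.append(
                KineticScheme(
                    name=sub.get("name"),
                    nodes=sub.get("nodes"),
                    state_variable=sub.get("stateVariable"),
                    edges=sub.get("edges"),
                    edge_source=sub.get("edgeSource", "from"),
                    edge_target=sub.get("edgeTarget", "to"),
                    forward_rate=sub.get("forwardRate"),
                    reverse_rate=sub.get("reverseRate"),
                )
            )
        else:
            raise SemanticError(f"{ctx}: unknown Dynamics sub-element {kind!r}")


def _parse_structure(el, ctx: str) -> list[StructureDirective]:
    out: list[StructureDirective] = []
    for sub in el:
        if not isinstance(sub.tag, str):
            continue
        kind = _local(sub)
        if kind == "MultiInstantiate":
            out.append(MultiInstantiate(sub.get("number"), sub.get("component")))
        elif kind == "ChildInstance":
            out.append(ChildInstance(sub.get("component")))
        elif kind == "EventConnection":
            out.append(
                EventConnection(
                    from_=sub.get("from"),
                    to=sub.get("to"),
                    source_port=sub.get("sourcePort"),
                    target_port=sub.get("targetPort"),
                    delay=sub.get("delay"),
                    weight=sub.get("weight"),
                    receiver=sub.get("receiver"),
                    receiver_container=sub.get("receiverContainer"),
                )
            )
        else:
            raise SemanticError(f"{ctx}: unknown Structure sub-element {kind!r}")
    return out


# --------------------------------------------------------------------------
# Component validation


def check_component(raw: RawComponent, doc: LemsDocument) -> TypedComponent:
    """Validate a raw component against its resolved type.

    Parameter attributes are parsed via the unit registry and
    dimension-checked; children are matched to slots by element name first,
    then by type compatibility, and arity is enforced.
    """
    rt = resolve_type(raw.type_name, doc)
    tc = TypedComponent(id=raw.id or raw.type_name, type=rt)
    errors: list[str] = []

    consumed: set[str] = set()
    for pname, pdim in rt.parameters.items():
        if pname not in raw.attributes:
            errors.append(f"component {tc.id!r}: missing parameter {pname!r}")
            continue
        consumed.add(pname)
        try:
            q = parse_quantity(raw.attributes[pname], doc.units)
        except UnitError as exc:
            errors.append(f"component {tc.id!r}: parameter {pname!r}: {exc}")
            continue
        if q.dimension != pdim:
            errors.append(
                f"component {tc.id!r}: parameter {pname!r} expects "
                f"{pdim.describe()}, got {q.dimension.describe()} "
                f"(value {raw.attributes[pname]!r})"
            )
            continue
        tc.parameters[pname] = q
    for tname in rt.texts:
        if tname in raw.attributes:
            tc.texts[tname] = raw.attributes[tname]
            consumed.add(tname)
    for rname in rt.component_refs:
        if rname in raw.attributes:
            tc.refs[rname] = raw.attributes[rname]
            consumed.add(rname)
        else:
            errors.append(f"component {tc.id!r}: missing component reference {rname!r}")
    for aname in raw.attributes:
        if aname not in consumed and aname != "type":
            errors.append(f"component {tc.id!r}: unknown attribute {aname!r}")

    # children -> slots
    for slot in rt.child_slots.values():
        tc.children.setdefault(slot.name, [])
    for rawchild in raw.children:
        slot = rt.child_slots.get(rawchild.type_name)
        if slot is not None:
            # slot-named element: concrete type from its 'type' attribute,
            # defaulting to the slot's declared type
            concrete = rawchild.attributes.get("type", slot.type_name)
            sub = RawComponent(
                concrete,
                rawchild.id or slot.name,
                {k: v for k, v in rawchild.attributes.items() if k != "type"},
                rawchild.children,
            )
            child_tc = check_component(sub, doc)
            if not child_tc.type.is_subtype_of(slot.type_name):
                errors.append(
                    f"component {tc.id!r}: child {rawchild.type_name!r} of type "
                    f"{concrete!r} does not extend {slot.type_name!r}"
                )
            tc.children[slot.name].append(child_tc)
            continue
        # type-named element: find a slot whose declared type is an ancestor
        try:
            child_rt = resolve_type(rawchild.type_name, doc)
        except SemanticError as exc:
            errors.append(f"component {tc.id!r}: {exc}")
            continue
        for slot in rt.child_slots.values():
            if child_rt.is_subtype_of(slot.type_name):
                tc.children[slot.name].append(check_component(rawchild, doc))
                break
        else:
            errors.append(
                f"component {tc.id!r}: child {rawchild.id!r} of type "
                f"{rawchild.type_name!r} fills no declared slot"
            )

    for slot in rt.child_slots.values():
        n = len(tc.children[slot.name])
        if slot.single and n != 1:
            errors.append(
                f"component {tc.id!r}: slot {slot.name!r} requires exactly one "
                f"child of type {slot.type_name!r}, found {n}"
            )

    if errors:
        raise SemanticError("; ".join(errors))
    return tc


# --------------------------------------------------------------------------
# Dynamics dimension checking


def _scope_dimensions(rt: ResolvedComponentType, doc: LemsDocument) -> dict[str, Dimension]:
    dims: dict[str, Dimension] = {"t": TIME}
    dims.update(rt.parameters)
    for name, (dim, _) in rt.derived_parameters.items():
        dims[name] = dim
    for name, q in rt.constants.items():
        dims[name] = q.dimension
    for name, c in doc.constants.items():
        dims.setdefault(name, c.quantity.dimension)
    dims.update(rt.requirements)
    dims.update(rt.dynamics.state_variables)
    for name, dv in rt.dynamics.derived_variables.items():
        dims[name] = dv.dimension
    return dims


def check_dynamics(rt: ResolvedComponentType, doc: LemsDocument) -> list[str]:
    """Dimension-check a resolved type's dynamics; returns all violations."""
    dyn = rt.dynamics
    dims = _scope_dimensions(rt, doc)
    report: list[str] = []
    ctx = f"type {rt.name!r}"

    def check_expr(expr: ex.Node, expected: Dimension, what: str) -> None:
        try:
            got = ex.infer_dimension(expr, dims)
        except ex.DimensionMismatch as exc:
            report.append(f"{ctx}: {what}: {exc}")
            return
        if got != expected:
            report.append(
                f"{ctx}: {what} has dimension {got.describe()}, "
                f"expected {expected.describe()}"
            )

    def check_derivs(tds: dict[str, ex.Node], where: str) -> None:
        for var, expr in tds.items():
            sdim = dyn.state_variables.get(var)
            if sdim is None:
                report.append(f"{ctx}: {where}TimeDerivative of unknown state {var!r}")
                continue
            check_expr(expr, dim_combine(sdim, TIME, "divide"), f"{where}d{var}/dt")

    def check_actions(actions: list[Action], where: str) -> None:
        for a in actions:
            if isinstance(a, StateAssign):
                sdim = dims.get(a.variable)
                if sdim is None:
                    report.append(f"{ctx}: {where}assignment to unknown variable {a.variable!r}")
                    continue
                check_expr(a.expr, sdim, f"{where}assignment to {a.variable}")
            elif isinstance(a, EventOut):
                if rt.event_ports.get(a.port) != "out":
                    report.append(f"{ctx}: {where}EventOut on non-out port {a.port!r}")
            elif isinstance(a, Transition):
                if a.regime not in dyn.regimes:
                    report.append(f"{ctx}: {where}transition to unknown regime {a.regime!r}")

    def check_conditions(handlers: list[ConditionHandler], where: str) -> None:
        for h in handlers:
            try:
                ex.check_condition_dimensions(h.test, dims)
            except ex.DimensionMismatch as exc:
                report.append(f"{ctx}: {where}condition: {exc}")
            check_actions(h.actions, where)

    check_derivs(dyn.time_derivatives, "")
    for name, dv in dyn.derived_variables.items():
        if dv.expr is not None:
            check_expr(dv.expr, dv.dimension, f"derived variable {name}")
        elif dv.reduce not in (None, "add", "multiply"):
            report.append(f"{ctx}: derived variable {name!r} has unknown reduce {dv.reduce!r}")
    check_actions(list(dyn.on_start), "OnStart ")
    for h in dyn.on_events:
        extra = dict(dims)
        extra["weight"] = DIMENSIONLESS
        for a in h.actions:
            if isinstance(a, StateAssign):
                sdim = dims.get(a.variable)
                if sdim is None:
                    report.append(f"{ctx}: OnEvent assignment to unknown variable {a.variable!r}")
                    continue
                try:
                    got = ex.infer_dimension(a.expr, extra)
                except ex.DimensionMismatch as exc:
                    report.append(f"{ctx}: OnEvent assignment: {exc}")
                    continue
                if got != sdim:
                    report.append(
                        f"{ctx}: OnEvent assignment to {a.variable} has dimension "
                        f"{got.describe()}, expected {sdim.describe()}"
                    )
        if rt.event_ports.get(h.port) != "in":
            report.append(f"{ctx}: OnEvent on non-in port {h.port!r}")
    check_conditions(dyn.on_conditions, "")

    for regime in dyn.regimes.values():
        where = f"regime {regime.name!r}: "
        check_derivs(regime.time_derivatives, where)
        check_actions(list(regime.on_entry), where + "OnEntry ")
        check_conditions(regime.on_conditions, where)
        for h in regime.on_events:
            check_actions(h.actions, where + "OnEvent ")

    if dyn.regimes:
        initial = [r for r in dyn.regimes.values() if r.initial]
        if len(initial) != 1:
            report.append(
                f"{ctx}: {len(initial)} regimes flagged initial; exactly one required"
            )

    # exposures must be backed by something evaluable
    backed = set(dyn.state_exposures.values())
    for dv in dyn.derived_variables.values():
        if dv.exposure:
            backed.add(dv.exposure)
    for name in rt.exposures:
        if name in backed or name in rt.parameters or name in rt.derived_parameters:
            continue
        if name in dyn.state_variables or name in dyn.derived_variables:
            continue
        if not dyn.empty:
            report.append(f"{ctx}: exposure {name!r} is not produced by the dynamics")
    return report


def check_document(doc: LemsDocument) -> list[str]:
    """Validate the whole document: every component type-checks and every
    concrete type's dynamics dimension-checks.  Returns all violations."""
    report = list(doc.errors)
    for raw in doc.components:
        if raw.type_name == "Simulation":
            continue
        try:
            tc = check_component(raw, doc)
        except (SemanticError, DocumentError) as exc:
            report.append(str(exc))
            continue
        seen: set[str] = set()

        def walk(t: TypedComponent) -> None:
            if t.type.name in seen:
                return
            seen.add(t.type.name)
            report.extend(check_dynamics(t.type, doc))
            for kids in t.children.values():
                for kid in kids:
                    walk(kid)

        walk(tc)
    return report
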