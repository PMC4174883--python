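"""Reading and writing LEMS XML documents.

A document's root element may contain exactly seven kinds of children:
``Target``, ``Include``, ``Dimension``, ``Unit``, ``Constant``,
``ComponentType`` and ``Component``.  Components may be written either as
``<Component type="T" .../>`` or with the type name as the tag
(``<T .../>``); both normalize to the same :class:`RawComponent`.
``Include`` elements are resolved depth-first against an ordered list of
search directories, each physical file loaded at most once, with cycle
detection.  XML namespaces are ignored (local names only).

Parsing here is schema-free and purely structural; expressions stay as
attribute strings and are interpreted by the semantics layer.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

from lxml import etree

from .units import (
    BASE_DIMENSION_ATTRS,
    Dimension,
    PhysicalConstant,
    Quantity,
    Unit,
    UnitError,
    parse_quantity,
    standard_dimensions,
)

__all__ = [
    "LemsDocument",
    "RawComponent",
    "RawComponentType",
    "parse_lems",
    "serialize_lems",
    "document_report",
    "DocumentError",
    "ROOT_ELEMENT_KINDS",
]

#: The seven legal root-level child element kinds.
ROOT_ELEMENT_KINDS = (
    "Target",
    "Include",
    "Dimension",
    "Unit",
    "Constant",
    "ComponentType",
    "Component",
)


class DocumentError(ValueError):
    """Malformed document: XML errors, missing includes, cycles, duplicates."""


# --------------------------------------------------------------------------
# Raw structural records


@dataclass
class RawComponent:
    """An untyped component element: id, type name, attributes, children."""

    type_name: str
    id: str | None
    attributes: dict[str, str]
    children: list["RawComponent"] = field(default_factory=list)

    def assign_synthetic_ids(self, parent_id: str = "") -> None:
        """Give anonymous components stable ids ``parentId_elementName_ordinal``."""
        counters: dict[str, int] = {}
        for child in self.children:
            if child.id is None:
                k = counters.get(child.type_name, 0)
                counters[child.type_name] = k + 1
                base = self.id or parent_id or "root"
                child.id = f"{base}_{child.type_name}_{k}"
            child.assign_synthetic_ids(self.id or parent_id)


@dataclass
class RawComponentType:
    """An unresolved ComponentType declaration, kept close to the XML.

    Sub-element records are (attribute-map, child-records) pairs; the
    semantics layer interprets them.
    """

    name: str
    extends: str | None
    element: etree._Element  # merged, namespace-free declaration


@dataclass
class LemsDocument:
    """A merged (post-include) model document."""

    targets: list[str] = field(default_factory=list)
    dimensions: dict[str, Dimension] = field(default_factory=standard_dimensions)
    units: dict[str, Unit] = field(default_factory=dict)
    constants: dict[str, PhysicalConstant] = field(default_factory=dict)
    component_types: dict[str, RawComponentType] = field(default_factory=dict)
    components: list[RawComponent] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)
    #: ordered root-level lxml elements, for faithful serialization
    _elements: list[etree._Element] = field(default_factory=list)

    def component_by_id(self, cid: str) -> RawComponent | None:
        for comp in self.components:
            if comp.id == cid:
                return comp
        return None


# --------------------------------------------------------------------------
# Parsing


def _local_name(el: etree._Element) -> str:
    return etree.QName(el).localname


def parse_lems(source: str | os.PathLike, include_dirs: list[str] | None = None) -> LemsDocument:
    """Parse a LEMS document from a file path or literal XML text.

    Strings containing ``<`` are treated as XML text; anything else as a
    path.  Includes are resolved against the including file's directory
    followed by ``include_dirs``, depth-first, each file loaded once.
    """
    include_dirs = [str(d) for d in (include_dirs or [])]
    elements: list[etree._Element] = []
    loaded: set[str] = set()

    if isinstance(source, str) and "<" in source:
        _load_xml_text(source, None, include_dirs, elements, loaded, stack=[])
    else:
        _load_file(str(source), include_dirs, elements, loaded, stack=[])

    return _build_document(elements)


def _load_file(path: str, include_dirs: list[str], elements, loaded: set[str], stack: list[str]) -> None:
    real = os.path.realpath(path)
    if real in stack:
        cycle = " -> ".join(stack + [real])
        raise DocumentError(f"include cycle: {cycle}")
    if real in loaded:
        return  # idempotent re-include
    if not os.path.exists(path):
        raise DocumentError(f"missing file {path!r}")
    loaded.add(real)
    try:
        tree = etree.parse(path)
    except etree.XMLSyntaxError as exc:
        raise DocumentError(f"malformed XML in {path!r}: {exc}") from None
    stack.append(real)
    try:
        _merge_root(tree.getroot(), os.path.dirname(real), include_dirs, elements, loaded, stack)
    finally:
        stack.pop()


def _load_xml_text(text: str, base_dir: str | None, include_dirs, elements, loaded, stack) -> None:
    try:
        root = etree.parse(io.BytesIO(text.encode("utf-8"))).getroot()
    except etree.XMLSyntaxError as exc:
        raise DocumentError(f"malformed XML: {exc}") from None
    _merge_root(root, base_dir, include_dirs, elements, loaded, stack)


def _merge_root(root, base_dir, include_dirs, elements, loaded, stack) -> None:
    if _local_name(root) != "Lems":
        raise DocumentError(f"root element is {_local_name(root)!r}, expected 'Lems'")
    for el in root:
        if not isinstance(el.tag, str):  # comments, PIs
            continue
        name = _local_name(el)
        if name == "Include":
            target = el.get("file") or el.get("href")
            if target is None:
                raise DocumentError("Include element without 'file' attribute")
            tried = []
            search = ([base_dir] if base_dir else []) + include_dirs
            for d in search:
                candidate = os.path.join(d, target)
                tried.append(candidate)
                if os.path.exists(candidate):
                    _load_file(candidate, include_dirs, elements, loaded, stack)
                    break
            else:
                raise DocumentError(
                    f"missing include file {target!r}; tried: {tried or ['<no search paths>']}"
                )
        else:
            elements.append(el)


def _build_document(elements: list[etree._Element]) -> LemsDocument:
    doc = LemsDocument()
    doc._elements = elements

    # first pass: dimensions and units (forward references allowed), type names
    for el in elements:
        name = _local_name(el)
        if name == "Dimension":
            _add_dimension(doc, el)
    for el in elements:
        name = _local_name(el)
        if name == "Unit":
            _add_unit(doc, el)
        elif name == "ComponentType":
            tname = el.get("name")
            if tname is None:
                raise DocumentError("ComponentType without a name")
            if tname in doc.component_types:
                raise DocumentError(f"duplicate ComponentType {tname!r}")
            doc.component_types[tname] = RawComponentType(tname, el.get("extends"), el)

    # second pass: everything else, in order
    seen_component_ids: set[str] = set()
    for el in elements:
        name = _local_name(el)
        if name in ("Dimension", "Unit", "ComponentType"):
            continue
        if name == "Target":
            comp = el.get("component")
            if comp is None:
                doc.errors.append("Target without 'component' attribute")
            else:
                doc.targets.append(comp)
        elif name == "Constant":
            _add_constant(doc, el)
        elif name == "Component" or name in doc.component_types:
            raw = _raw_component(el, doc)
            if raw.id is not None:
                if raw.id in seen_component_ids:
                    raise DocumentError(f"duplicate component id {raw.id!r}")
                seen_component_ids.add(raw.id)
            doc.components.append(raw)
        elif name == "Simulation":
            # the built-in simulation component kind
            raw = _raw_component(el, doc)
            doc.components.append(raw)
        else:
            doc.errors.append(f"unknown root-level element {name!r}")

    for comp in doc.components:
        comp.assign_synthetic_ids()

    for target in doc.targets:
        if not any(c.id == target for c in doc.components):
            doc.errors.append(f"Target {target!r} does not name a top-level component")
    return doc


def _add_dimension(doc: LemsDocument, el) -> None:
    name = el.get("name")
    if name is None:
        raise DocumentError("Dimension without a name")
    exps = []
    for attr in BASE_DIMENSION_ATTRS:
        raw = el.get(attr, "0")
        try:
            f = float(raw)
        except ValueError:
            raise DocumentError(f"dimension {name!r}: bad exponent {raw!r}") from None
        if not f.is_integer():
            raise DocumentError(f"dimension {name!r}: non-integer exponent {raw!r}")
        exps.append(int(f))
    dim = Dimension(name, tuple(exps))
    existing = doc.dimensions.get(name)
    if existing is not None and existing.exponents != dim.exponents:
        raise DocumentError(f"duplicate dimension {name!r} with conflicting exponents")
    doc.dimensions[name] = dim


def _add_unit(doc: LemsDocument, el) -> None:
    symbol = el.get("symbol")
    dimname = el.get("dimension")
    if symbol is None or dimname is None:
        raise DocumentError("Unit needs 'symbol' and 'dimension' attributes")
    if dimname not in doc.dimensions:
        raise DocumentError(f"unit {symbol!r} references unknown dimension {dimname!r}")
    if symbol in doc.units:
        raise DocumentError(f"duplicate unit symbol {symbol!r}")
    power = int(el.get("power", "0"))
    scale = float(el.get("scale", "1"))
    offset = float(el.get("offset", "0"))
    doc.units[symbol] = Unit(symbol, doc.dimensions[dimname], power, scale, offset)


def _add_constant(doc: LemsDocument, el) -> None:
    name = el.get("name")
    value = el.get("value")
    if name is None or value is None:
        raise DocumentError("Constant needs 'name' and 'value' attributes")
    try:
        q = parse_quantity(value, doc.units)
    except UnitError as exc:
        raise DocumentError(f"constant {name!r}: {exc}") from None
    dimname = el.get("dimension")
    if dimname is not None:
        declared = doc.dimensions.get(dimname)
        if declared is None:
            raise DocumentError(f"constant {name!r} references unknown dimension {dimname!r}")
        if declared != q.dimension:
            raise DocumentError(
                f"constant {name!r}: value dimension {q.dimension.describe()} does "
                f"not match declared {declared.describe()}"
            )
        q = Quantity(q.magnitude, declared)
    if name in doc.constants:
        raise DocumentError(f"duplicate constant {name!r}")
    doc.constants[name] = PhysicalConstant(name, q)


def _raw_component(el, doc: LemsDocument) -> RawComponent:
    name = _local_name(el)
    attrs = {k: v for k, v in el.attrib.items()}
    if name == "Component":
        type_name = attrs.pop("type", None)
        if type_name is None:
            raise DocumentError("Component element without a 'type' attribute")
    else:
        type_name = name
    cid = attrs.pop("id", None)
    children = [
        _raw_component(sub, doc) for sub in el if isinstance(sub.tag, str)
    ]
    return RawComponent(type_name, cid, attrs, children)


# --------------------------------------------------------------------------
# Serialization


def serialize_lems(doc: LemsDocument) -> str:
    """Write the merged document back to XML text.

    Includes were already merged at parse time, so the output is a single
    self-contained document with a provenance comment.
    """
    root = etree.Element("Lems")
    root.append(etree.Comment(" includes resolved and merged at load time "))
    for el in doc._elements:
        root.append(_strip_ns(el))
    return etree.tostring(
        root, pretty_print=True, encoding="unicode"
    )


def _strip_ns(el: etree._Element) -> etree._Element:
    out = etree.Element(_local_name(el))
    for k, v in el.attrib.items():
        out.set(etree.QName(k).localname if "}" in k else k, v)
    if el.text and el.text.strip():
        out.text = el.text
    for sub in el:
        if isinstance(sub.tag, str):
            out.append(_strip_ns(sub))
    return out


def structurally_equal(a: LemsDocument, b: LemsDocument) -> bool:
    """Deep structural equality: element names, attributes, child order."""

    def canon(el):
        return (
            _local_name(el),
            dict(el.attrib),
            [canon(sub) for sub in el if isinstance(sub.tag, str)],
        )

    return [canon(e) for e in a._elements] == [canon(e) for e in b._elements]


# --------------------------------------------------------------------------
# Reporting


def document_report(doc: LemsDocument) -> dict:
    """Counts per root element kind, targets, and unresolved references."""
    unresolved = list(doc.errors)
    for comp in doc.components:
        if comp.type_name not in doc.component_types and comp.type_name != "Simulation":
            unresolved.append(
                f"component {comp.id!r} has undeclared type {comp.type_name!r}"
            )
    n_custom_dims = sum(
        1 for name in doc.dimensions if name not in standard_dimensions()
    )
    return {
        "targets": list(doc.targets),
        "dimensions": n_custom_dims,
        "units": len(doc.units),
        "constants": len(doc.constants),
        "component_types": len(doc.component_types),
        "components": len(doc.components),
        "unresolved": unresolved,
    }
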