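"""The modeling language: parsing, convention defaults, inheritance,
validation, load ordering and canonical serialization.

The DSL is XML.  One document declares one application::

    <molgenis name="microbe_lab">
      <entity name="Experiment">
        <field name="ID" unique="true"/>
        <field name="Medium"/>
        <field name="Temperature" type="decimal" nillable="true"/>
      </entity>
      <entity name="Sample">
        <field name="ID" unique="true"/>
        <field name="Experiment" type="xref" xref_entity="Experiment" xref_field="ID"/>
      </entity>
      <ui>
        <form name="Experiments" entity="Experiment">
          <menu name="Details">
            <form name="Samples" entity="Sample" view="list"/>
          </menu>
        </form>
      </ui>
    </molgenis>

Unset attributes receive convention-over-configuration defaults
(:func:`apply_defaults`): type ``string``, length 255, required (not
nillable), editable (not readonly), not unique, label = name, forms show one
record per screen.  Cross-references (``xref``) must target a unique field of
the referenced entity and map to relational foreign keys downstream.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET

import networkx as nx

from .errors import ModelError, ParseError
from .model import (
    FIELD_TYPES,
    UNSET,
    Entity,
    Field,
    Model,
    UIElement,
    ValidationIssue,
)

# ---------------------------------------------------------------------------
# parsing

_ENTITY_ATTRS = {"name", "label", "description", "extends"}
_FIELD_ATTRS = {
    "name", "type", "nillable", "readonly", "unique", "length",
    "xref_entity", "xref_field", "label", "description", "default",
}
_FORM_ATTRS = {"name", "entity", "view", "link"}
_MENU_ATTRS = {"name", "label"}
_PLUGIN_ATTRS = {"name", "id"}
_ROOT_ATTRS = {"name"}

_BOOL = {"true": True, "false": False}


def _attr_bool(el: ET.Element, name: str, issues, strict: bool, locus: str):
    raw = el.get(name)
    if raw is None:
        return UNSET
    if raw not in _BOOL:
        raise ParseError(
            f"attribute {name}={raw!r} at {locus}: expected 'true' or 'false'"
        )
    return _BOOL[raw]


def _check_unknown(el: ET.Element, allowed: set[str], locus: str,
                   strict: bool, warnings: list[ValidationIssue]) -> None:
    for attr in el.attrib:
        if attr not in allowed:
            msg = f"unknown attribute {attr!r} on <{el.tag}>"
            if strict:
                raise ParseError(msg, code="UNKNOWN_MARKUP")
            warnings.append(ValidationIssue("warning", "UNKNOWN_MARKUP", locus, msg))


def _require(el: ET.Element, attr: str, locus: str) -> str:
    value = el.get(attr)
    if value is None or not value.strip():
        raise ParseError(f"<{el.tag}> at {locus} requires attribute {attr!r}")
    return value.strip()


def _parse_field(el: ET.Element, entity_name: str, strict: bool,
                 warnings: list[ValidationIssue]) -> Field:
    name = _require(el, "name", f"entity:{entity_name}")
    locus = f"entity:{entity_name}/field:{name}"
    _check_unknown(el, _FIELD_ATTRS, locus, strict, warnings)
    length = el.get("length")
    if length is not None:
        try:
            length = int(length)
        except ValueError:
            raise ParseError(f"length={length!r} at {locus} is not an integer") from None
    return Field(
        name=name,
        type=el.get("type", UNSET) if el.get("type") is not None else UNSET,
        nillable=_attr_bool(el, "nillable", warnings, strict, locus),
        readonly=_attr_bool(el, "readonly", warnings, strict, locus),
        unique=_attr_bool(el, "unique", warnings, strict, locus),
        max_length=length if length is not None else UNSET,
        xref_entity=el.get("xref_entity", UNSET) if el.get("xref_entity") is not None else UNSET,
        xref_field=el.get("xref_field", UNSET) if el.get("xref_field") is not None else UNSET,
        label=el.get("label", UNSET) if el.get("label") is not None else UNSET,
        description=el.get("description", UNSET) if el.get("description") is not None else UNSET,
        default_value=el.get("default", UNSET) if el.get("default") is not None else UNSET,
        defined_in=entity_name,
    )


def _parse_ui_element(el: ET.Element, strict: bool,
                      warnings: list[ValidationIssue], path: str) -> UIElement:
    if el.tag == "menu":
        name = _require(el, "name", path)
        locus = f"{path}/menu:{name}"
        _check_unknown(el, _MENU_ATTRS, locus, strict, warnings)
        element = UIElement(kind="menu", name=name)
    elif el.tag == "form":
        name = _require(el, "name", path)
        locus = f"{path}/form:{name}"
        _check_unknown(el, _FORM_ATTRS, locus, strict, warnings)
        view = el.get("view")
        if view is not None and view not in ("record", "list"):
            raise ParseError(f"view={view!r} at {locus}: expected 'record' or 'list'")
        element = UIElement(
            kind="form",
            name=name,
            entity=_require(el, "entity", locus),
            view_mode=view if view is not None else UNSET,
            link_field=el.get("link", UNSET) if el.get("link") is not None else UNSET,
        )
    elif el.tag == "plugin":
        name = _require(el, "name", path)
        locus = f"{path}/plugin:{name}"
        _check_unknown(el, _PLUGIN_ATTRS, locus, strict, warnings)
        element = UIElement(kind="plugin", name=name, plugin_id=_require(el, "id", locus))
    else:
        msg = f"unknown element <{el.tag}> under {path}"
        if strict:
            raise ParseError(msg, code="UNKNOWN_MARKUP")
        warnings.append(ValidationIssue("warning", "UNKNOWN_MARKUP", path, msg))
        return None  # type: ignore[return-value]
    if el.tag == "plugin" and len(el):
        raise ParseError(f"<plugin> at {path} may not have children")
    for child in el:
        parsed = _parse_ui_element(child, strict, warnings, locus)
        if parsed is not None:
            element.children.append(parsed)
    return element


def parse_model(xml_text: str, strict: bool = True) -> Model:
    """Parse a DSL document into a raw :class:`Model`.

    Attributes absent from the document stay ``UNSET``; convention defaults
    are applied later by :func:`apply_defaults`.  Element order is preserved.

    Parameters
    ----------
    xml_text:
        The document text.
    strict:
        When true (default) unknown elements or attributes raise
        :class:`~entigen.errors.ParseError`; when false they are collected as
        warnings on ``model.parse_warnings``.
    """
    try:
        root = ET.parse(io.StringIO(xml_text)).getroot()
    except ET.ParseError as exc:
        line = exc.position[0] if exc.position else None
        raise ParseError(f"malformed XML: {exc.msg if hasattr(exc, 'msg') else exc} "
                         f"(line {line})", line=line) from None

    if root.tag != "molgenis":
        raise ParseError(f"root element must be <molgenis>, got <{root.tag}>")

    warnings: list[ValidationIssue] = []
    _check_unknown(root, _ROOT_ATTRS, "model", strict, warnings)
    model = Model(name=root.get("name", "unnamed"))

    for child in root:
        if child.tag == "entity":
            ename = _require(child, "name", "model")
            locus = f"entity:{ename}"
            _check_unknown(child, _ENTITY_ATTRS, locus, strict, warnings)
            entity = Entity(
                name=ename,
                label=child.get("label", UNSET) if child.get("label") is not None else UNSET,
                description=child.get("description", UNSET)
                if child.get("description") is not None else UNSET,
                extends=child.get("extends", UNSET)
                if child.get("extends") is not None else UNSET,
            )
            for sub in child:
                if sub.tag == "field":
                    entity.fields.append(_parse_field(sub, ename, strict, warnings))
                else:
                    msg = f"unknown element <{sub.tag}> in {locus}"
                    if strict:
                        raise ParseError(msg, code="UNKNOWN_MARKUP")
                    warnings.append(ValidationIssue("warning", "UNKNOWN_MARKUP", locus, msg))
            model.entities.append(entity)
        elif child.tag == "ui":
            for sub in child:
                parsed = _parse_ui_element(sub, strict, warnings, "ui")
                if parsed is not None:
                    model.ui.append(parsed)
        else:
            msg = f"unknown element <{child.tag}> under <molgenis>"
            if strict:
                raise ParseError(msg, code="UNKNOWN_MARKUP")
            warnings.append(ValidationIssue("warning", "UNKNOWN_MARKUP", "model", msg))

    model.parse_warnings = warnings
    return model


# ---------------------------------------------------------------------------
# convention over configuration

def apply_defaults(model: Model) -> Model:
    """Return a copy with every unset attribute replaced by its convention value.

    Conventions: type ``string``; strings carry ``max_length`` 255; fields are
    required (``nillable`` false), editable (``readonly`` false) and not
    ``unique``; labels default to names; descriptions to the empty string;
    forms show one record per screen.  Idempotent; never overwrites an
    explicitly set attribute.
    """
    out = model.copy()
    for entity in out.entities:
        if entity.label is UNSET:
            entity.label = entity.name
        if entity.description is UNSET:
            entity.description = ""
        for f in entity.fields:
            if f.type is UNSET:
                f.type = "string"
            if f.type == "string" and f.max_length is UNSET:
                f.max_length = 255
            if f.nillable is UNSET:
                f.nillable = False
            if f.readonly is UNSET:
                f.readonly = False
            if f.unique is UNSET:
                f.unique = False
            if f.label is UNSET:
                f.label = f.name
            if f.description is UNSET:
                f.description = ""
            if f.defined_in is UNSET:
                f.defined_in = entity.name
    for _, el in out.walk_ui():
        if el.kind == "form" and el.view_mode is UNSET:
            el.view_mode = "record"
    return out


# ---------------------------------------------------------------------------
# inheritance

def _ancestry(model: Model, entity: Entity) -> list[Entity]:
    """Ancestor chain root-first, excluding *entity* itself.

    Raises on unknown parents and cycles.
    """
    chain: list[Entity] = []
    seen = {entity.name.lower()}
    current = entity
    while current.extends not in (UNSET, None, ""):
        parent = model.entity(current.extends)  # type: ignore[arg-type]
        if parent is None:
            raise ModelError(
                "EXTENDS_UNKNOWN",
                f"entity {current.name!r} extends unknown entity {current.extends!r}",
            )
        if parent.name.lower() in seen:
            cycle = " -> ".join([e.name for e in [entity, *chain]] + [parent.name])
            raise ModelError("MODEL_INHERITANCE_CYCLE",
                             f"inheritance cycle: {cycle}")
        seen.add(parent.name.lower())
        chain.append(parent)
        current = parent
    chain.reverse()
    return chain


def resolve_inheritance(model: Model) -> Model:
    """Return a copy where each entity's field list is flattened.

    The flattened list is the parent's flattened fields (in order) followed by
    the entity's own fields; the ``extends`` marker is retained for
    documentation.  A child may not redeclare a parent field name.
    """
    out = model.copy()
    for entity in out.entities:
        ancestors = _ancestry(out, entity)
        flattened: list[Field] = []
        seen: set[str] = set()
        for ancestor in ancestors + [entity]:
            for f in ancestor.own_fields:
                if f.name.lower() in seen:
                    raise ModelError(
                        "FIELD_REDECLARED",
                        f"field {f.name!r} of entity {entity.name!r} redeclares "
                        f"an inherited field",
                    )
                seen.add(f.name.lower())
                flattened.append(f.copy())
        entity.fields = flattened
    return out


# ---------------------------------------------------------------------------
# validation

def _xref_edges(model: Model):
    """Yield (source entity, target entity, field) for each resolvable
    non-self xref, preserving model order."""
    for entity in model.entities:
        for f in entity.fields:
            if f.type == "xref" and f.xref_entity not in (UNSET, None):
                target = model.entity(f.xref_entity)  # type: ignore[arg-type]
                if target is not None and target.name.lower() != entity.name.lower():
                    yield entity, target, f


def validate(model: Model) -> list[ValidationIssue]:
    """Check every model invariant; empty result means the model is valid.

    Expects convention defaults to be applied.  Inheritance may or may not be
    resolved already: resolution is attempted internally so that inheritance
    defects surface as issues rather than exceptions.  Issues are
    deterministic and ordered by model position.
    """
    issues: list[ValidationIssue] = []

    # entity name uniqueness (case-insensitive)
    seen: dict[str, str] = {}
    for entity in model.entities:
        low = entity.name.lower()
        if low in seen:
            issues.append(ValidationIssue(
                "error", "ENTITY_DUPLICATE", f"entity:{entity.name}",
                f"entity name {entity.name!r} duplicates {seen[low]!r} "
                f"(names are case-insensitive)"))
        else:
            seen[low] = entity.name

    # inheritance: unknown parents, cycles, redeclared fields; flatten a copy
    try:
        flat = resolve_inheritance(model)
    except ModelError as exc:
        # re-run per entity to attribute the issue to a locus
        flat = None
        for entity in model.entities:
            single = model.copy()
            try:
                target = single.entity(entity.name)
                assert target is not None
                _ancestry(single, target)
                # check redeclaration against resolved ancestors
                names: set[str] = set()
                for anc in _ancestry(single, target) + [target]:
                    for f in anc.own_fields:
                        if f.name.lower() in names:
                            raise ModelError(
                                "FIELD_REDECLARED",
                                f"field {f.name!r} of entity {entity.name!r} "
                                f"redeclares an inherited field")
                        names.add(f.name.lower())
            except ModelError as entity_exc:
                issues.append(ValidationIssue(
                    "error", entity_exc.code, f"entity:{entity.name}",
                    entity_exc.message))
        if not any(i.code == exc.code for i in issues):  # pragma: no cover
            issues.append(ValidationIssue("error", exc.code, "model", exc.message))

    check = flat if flat is not None else model

    # duplicate own-field names inside a single entity (pre-flattening defect)
    for entity in model.entities:
        names2: set[str] = set()
        for f in entity.own_fields:
            if f.name.lower() in names2:
                issues.append(ValidationIssue(
                    "error", "FIELD_REDECLARED",
                    f"entity:{entity.name}/field:{f.name}",
                    f"field name {f.name!r} declared twice in entity {entity.name!r}"))
            names2.add(f.name.lower())

    # per-field attribute invariants and xref resolution
    for entity in check.entities:
        for f in entity.fields:
            locus = f"entity:{entity.name}/field:{f.name}"
            if f.type not in FIELD_TYPES:
                issues.append(ValidationIssue(
                    "error", "FIELD_ATTR_INVALID", locus,
                    f"unknown type {f.type!r}; expected one of {', '.join(FIELD_TYPES)}"))
                continue
            if f.type == "xref":
                if f.xref_entity in (UNSET, None) or f.xref_field in (UNSET, None):
                    issues.append(ValidationIssue(
                        "error", "FIELD_ATTR_INVALID", locus,
                        "xref fields require both xref_entity and xref_field"))
                    continue
            else:
                if f.xref_entity not in (UNSET, None) or f.xref_field not in (UNSET, None):
                    issues.append(ValidationIssue(
                        "error", "FIELD_ATTR_INVALID", locus,
                        f"xref_entity/xref_field are only valid on xref fields, "
                        f"not type {f.type!r}"))
            if f.type == "string":
                if not (isinstance(f.max_length, int) and f.max_length >= 1):
                    issues.append(ValidationIssue(
                        "error", "FIELD_ATTR_INVALID", locus,
                        f"string field needs max_length >= 1, got {f.max_length!r}"))
            elif f.max_length is not UNSET:
                issues.append(ValidationIssue(
                    "error", "FIELD_ATTR_INVALID", locus,
                    f"max_length is only valid on string fields, not {f.type!r}"))

            if f.type == "xref" and f.xref_entity not in (UNSET, None):
                target = check.entity(f.xref_entity)  # type: ignore[arg-type]
                if target is None:
                    issues.append(ValidationIssue(
                        "error", "XREF_TARGET_MISSING", locus,
                        f"xref target entity {f.xref_entity!r} does not exist"))
                    continue
                tfield = target.field(f.xref_field)  # type: ignore[arg-type]
                if tfield is None:
                    issues.append(ValidationIssue(
                        "error", "XREF_TARGET_MISSING", locus,
                        f"xref target field {f.xref_entity}.{f.xref_field} "
                        f"does not exist"))
                    continue
                if tfield.type == "xref":
                    issues.append(ValidationIssue(
                        "error", "SCHEMA_XREF_CHAIN", locus,
                        f"xref target {f.xref_entity}.{f.xref_field} is itself an "
                        f"xref field; chains are unsupported"))
                elif tfield.unique is not True:
                    issues.append(ValidationIssue(
                        "error", "XREF_TARGET_NOT_UNIQUE", locus,
                        f"xref target {f.xref_entity}.{f.xref_field} is not "
                        f"declared unique"))
                # self-reference must be nillable so rows can be loaded at all
                if (target.name.lower() == entity.name.lower()
                        and f.nillable is not True):
                    issues.append(ValidationIssue(
                        "error", "MODEL_XREF_CYCLE", locus,
                        f"self-referencing xref {entity.name}.{f.name} must be "
                        f"nillable"))

    # inter-entity xref cycles: an error unless at least one edge on every
    # cycle is nillable (soft); precisely, the graph of non-nillable xrefs
    # must be acyclic
    if not any(i.severity == "error" for i in issues):
        hard = nx.DiGraph()
        hard.add_nodes_from(e.name for e in check.entities)
        for source, target, f in _xref_edges(check):
            if f.nillable is not True:
                hard.add_edge(target.name, source.name)
        for scc in nx.strongly_connected_components(hard):
            if len(scc) > 1:
                members = sorted(scc)
                issues.append(ValidationIssue(
                    "error", "MODEL_XREF_CYCLE", f"entity:{members[0]}",
                    "cycle of non-nillable cross-references between entities: "
                    + ", ".join(members)))

    # user interface
    def _check_ui(elements: list[UIElement], parent_form: UIElement | None, path: str):
        sibling_names: set[str] = set()
        for el in elements:
            locus = f"{path}/{el.kind}:{el.name}"
            if el.name.lower() in sibling_names:
                issues.append(ValidationIssue(
                    "error", "UI_DUPLICATE_NAME", locus,
                    f"ui element name {el.name!r} duplicated among siblings"))
            sibling_names.add(el.name.lower())
            next_parent = parent_form
            if el.kind == "form":
                entity = check.entity(el.entity)  # type: ignore[arg-type]
                if entity is None:
                    issues.append(ValidationIssue(
                        "error", "UI_ENTITY_UNKNOWN", locus,
                        f"form {el.name!r} references unknown entity {el.entity!r}"))
                elif parent_form is not None:
                    parent_entity = check.entity(parent_form.entity)  # type: ignore[arg-type]
                    if parent_entity is not None:
                        _check_form_link(el, entity, parent_entity, locus)
                next_parent = el if el.kind == "form" else parent_form
            _check_ui(el.children, next_parent, locus)

    def _check_form_link(el: UIElement, entity: Entity, parent_entity: Entity,
                         locus: str):
        if el.link_field not in (UNSET, None):
            f = entity.field(el.link_field)  # type: ignore[arg-type]
            if f is None or f.type != "xref" or f.xref_entity in (UNSET, None) \
                    or f.xref_entity.lower() != parent_entity.name.lower():
                issues.append(ValidationIssue(
                    "error", "UI_LINK_UNKNOWN_FIELD", locus,
                    f"declared link field {el.link_field!r} is not an xref of "
                    f"{entity.name!r} targeting {parent_entity.name!r}"))
            return
        candidates = [f for f in entity.fields
                      if f.type == "xref" and f.xref_entity not in (UNSET, None)
                      and f.xref_entity.lower() == parent_entity.name.lower()]
        if not candidates:
            issues.append(ValidationIssue(
                "error", "UI_NO_LINK", locus,
                f"child form entity {entity.name!r} has no xref to parent form "
                f"entity {parent_entity.name!r}"))
        elif len(candidates) > 1:
            issues.append(ValidationIssue(
                "error", "UI_AMBIGUOUS_LINK", locus,
                f"child form entity {entity.name!r} has {len(candidates)} xrefs to "
                f"parent form entity {parent_entity.name!r}; declare an explicit "
                f"link field"))

    _check_ui(model.ui, None, "ui")
    return issues


# ---------------------------------------------------------------------------
# load order

def entity_load_order(model: Model) -> list[str]:
    """Order entities so that every cross-referenced entity precedes its
    referrers.

    Self-referencing xrefs are ignored.  Nillable ("soft") xref edges that
    participate in a cycle are relaxed — batch import resolves them in a
    second pass — while a cycle of non-nillable edges is an error.  Ties are
    broken by declaration order, which makes the result the unique
    declaration-order-minimal topological order.
    """
    index = {e.name: i for i, e in enumerate(model.entities)}

    hard = nx.DiGraph()
    full = nx.DiGraph()
    for g in (hard, full):
        g.add_nodes_from(index)
    soft_edges: set[tuple[str, str]] = set()
    for source, target, f in _xref_edges(model):
        full.add_edge(target.name, source.name)
        if f.nillable is True:
            soft_edges.add((target.name, source.name))
        else:
            hard.add_edge(target.name, source.name)
            soft_edges.discard((target.name, source.name))

    for scc in nx.strongly_connected_components(hard):
        if len(scc) > 1:
            members = sorted(scc)
            raise ModelError(
                "MODEL_XREF_CYCLE",
                "cycle of non-nillable cross-references between entities: "
                + ", ".join(members))

    # drop soft edges inside cyclic components; all other edges are honored
    sccs = list(nx.strongly_connected_components(full))
    component = {}
    for i, scc in enumerate(sccs):
        for name in scc:
            component[name] = i
    graph = nx.DiGraph()
    graph.add_nodes_from(index)
    for u, v in full.edges:
        if (u, v) in soft_edges and component[u] == component[v] \
                and len(sccs[component[u]]) > 1:
            continue
        graph.add_edge(u, v)

    # Kahn's algorithm, smallest declaration index first
    indegree = {n: graph.in_degree(n) for n in graph.nodes}
    ready = sorted((n for n, d in indegree.items() if d == 0), key=index.__getitem__)
    order: list[str] = []
    while ready:
        node = ready.pop(0)
        order.append(node)
        for succ in graph.successors(node):
            indegree[succ] -= 1
            if indegree[succ] == 0:
                ready.append(succ)
        ready.sort(key=index.__getitem__)
    assert len(order) == len(index), "cycle survived relaxation"
    return order


# ---------------------------------------------------------------------------
# serialization

_FIELD_DEFAULTS_OMIT = {"nillable": False, "readonly": False, "unique": False}


def _set_if(el: ET.Element, attr: str, value) -> None:
    if value not in (UNSET, None):
        el.set(attr, value if isinstance(value, str) else
               ("true" if value is True else "false" if value is False else str(value)))


def serialize_model(model: Model) -> str:
    """Serialize to canonical DSL text: attributes equal to their convention
    default are omitted, and only fields an entity declares itself (not
    inherited copies) are written, so ``parse_model(serialize_model(m))`` is
    semantically equal to ``m``.
    """
    root = ET.Element("molgenis", {"name": model.name})
    for entity in model.entities:
        eel = ET.SubElement(root, "entity", {"name": entity.name})
        if entity.extends not in (UNSET, None):
            eel.set("extends", entity.extends)
        if entity.label not in (UNSET, None) and entity.label != entity.name:
            eel.set("label", entity.label)
        if entity.description not in (UNSET, None, ""):
            eel.set("description", entity.description)
        for f in entity.own_fields:
            fel = ET.SubElement(eel, "field", {"name": f.name})
            if f.type not in (UNSET, None, "string"):
                fel.set("type", f.type)
            if f.type in ("string", UNSET, None) and \
                    isinstance(f.max_length, int) and f.max_length != 255:
                fel.set("length", str(f.max_length))
            for attr, default in _FIELD_DEFAULTS_OMIT.items():
                value = getattr(f, attr)
                if value not in (UNSET, default):
                    _set_if(fel, attr, value)
            _set_if(fel, "xref_entity", f.xref_entity)
            _set_if(fel, "xref_field", f.xref_field)
            if f.label not in (UNSET, None) and f.label != f.name:
                fel.set("label", f.label)
            if f.description not in (UNSET, None, ""):
                fel.set("description", f.description)
            _set_if(fel, "default", f.default_value)
    if model.ui:
        uel = ET.SubElement(root, "ui")
        def emit(parent_el: ET.Element, element: UIElement) -> None:
            if element.kind == "menu":
                el = ET.SubElement(parent_el, "menu", {"name": element.name})
            elif element.kind == "form":
                el = ET.SubElement(parent_el, "form",
                                   {"name": element.name, "entity": element.entity})
                if element.view_mode not in (UNSET, None, "record"):
                    el.set("view", element.view_mode)
                _set_if(el, "link", element.link_field)
            else:
                el = ET.SubElement(parent_el, "plugin",
                                   {"name": element.name, "id": element.plugin_id})
            for child in element.children:
                emit(el, child)
        for element in model.ui:
            emit(uel, element)
    ET.indent(root, space="  ")
    return ET.tostring(root, encoding="unicode", xml_declaration=False) + "\n"


# ---------------------------------------------------------------------------
# convenience pipeline

def models_equal(a: Model, b: Model) -> bool:
    """Structural equality after normalization (defaults applied, inheritance
    resolved)."""
    na = resolve_inheritance(apply_defaults(a))
    nb = resolve_inheritance(apply_defaults(b))
    return na == nb


def compile_model(xml_text: str, strict: bool = True) -> Model:
    """Parse, default-fill, validate and inheritance-resolve in one step.

    Raises :class:`ModelError` carrying the first issue's code if validation
    finds any error.
    """
    model = apply_defaults(parse_model(xml_text, strict=strict))
    issues = [i for i in validate(model) if i.severity == "error"]
    if issues:
        raise ModelError(issues[0].code,
                         "; ".join(str(i) for i in issues))
    return resolve_inheritance(model)
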