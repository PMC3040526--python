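"""Domain types of the modeling language.

A :class:`Model` is the in-memory form of one DSL document: named data
entities (typed fields, cross-references, inheritance) plus a declarative
user-interface tree (menus, forms, plugins).  Attributes a document does not
set stay :data:`UNSET` until :func:`entigen.dsl.apply_defaults` fills in the
convention values, so "explicitly false" and "never stated" remain
distinguishable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Iterator, Optional, Union


class _Unset:
    """Sentinel for attributes absent from the source document."""

    _instance: Optional["_Unset"] = None

    def __new__(cls) -> "_Unset":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - repr cosmetics
        return "UNSET"

    def __bool__(self) -> bool:
        return False


UNSET = _Unset()

#: Field types of the DSL. ``string`` is the convention default.
FIELD_TYPES = ("string", "text", "int", "decimal", "bool", "date", "xref")


@dataclass
class Field:
    name: str
    type: Union[str, _Unset] = UNSET
    nillable: Union[bool, _Unset] = UNSET
    readonly: Union[bool, _Unset] = UNSET
    unique: Union[bool, _Unset] = UNSET
    max_length: Union[int, _Unset] = UNSET      # string type only
    xref_entity: Union[str, _Unset] = UNSET     # xref type only
    xref_field: Union[str, _Unset] = UNSET      # xref type only
    label: Union[str, _Unset] = UNSET
    description: Union[str, _Unset] = UNSET
    default_value: Union[str, _Unset] = UNSET
    #: name of the entity that declared this field (set by the parser;
    #: inherited copies keep their declaring ancestor's name)
    defined_in: Union[str, _Unset] = UNSET

    def copy(self) -> "Field":
        return dataclasses.replace(self)


@dataclass
class Entity:
    name: str
    label: Union[str, _Unset] = UNSET
    description: Union[str, _Unset] = UNSET
    extends: Union[str, _Unset] = UNSET
    fields: list[Field] = dc_field(default_factory=list)

    def field(self, name: str) -> Optional[Field]:
        """Case-insensitive field lookup."""
        low = name.lower()
        for f in self.fields:
            if f.name.lower() == low:
                return f
        return None

    @property
    def own_fields(self) -> list[Field]:
        """Fields declared on this entity itself (excludes inherited copies)."""
        return [f for f in self.fields if f.defined_in in (UNSET, self.name)]

    def key_field(self) -> Optional[Field]:
        """The entity's row identity: its first unique field, in model order."""
        for f in self.fields:
            if f.unique is True:
                return f
        return None

    def copy(self) -> "Entity":
        return dataclasses.replace(self, fields=[f.copy() for f in self.fields])


@dataclass
class UIElement:
    kind: str                                   # menu | form | plugin
    name: str
    entity: Union[str, _Unset] = UNSET          # form only
    view_mode: Union[str, _Unset] = UNSET       # form only: record | list
    link_field: Union[str, _Unset] = UNSET      # form only: explicit parent link
    plugin_id: Union[str, _Unset] = UNSET       # plugin only
    children: list["UIElement"] = dc_field(default_factory=list)

    def walk(self) -> Iterator["UIElement"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def copy(self) -> "UIElement":
        return dataclasses.replace(self, children=[c.copy() for c in self.children])


@dataclass
class Model:
    name: str
    entities: list[Entity] = dc_field(default_factory=list)
    ui: list[UIElement] = dc_field(default_factory=list)
    #: warnings collected during lax parsing (unknown markup)
    parse_warnings: list["ValidationIssue"] = dc_field(default_factory=list, compare=False)

    def entity(self, name: str) -> Optional[Entity]:
        """Case-insensitive entity lookup."""
        low = name.lower()
        for e in self.entities:
            if e.name.lower() == low:
                return e
        return None

    def walk_ui(self) -> Iterator[tuple[Optional[UIElement], UIElement]]:
        """Yield (parent, element) over the whole UI tree, depth-first."""

        def rec(parent: Optional[UIElement], elems: list[UIElement]):
            for el in elems:
                yield parent, el
                yield from rec(el, el.children)

        yield from rec(None, self.ui)

    def copy(self) -> "Model":
        return Model(
            name=self.name,
            entities=[e.copy() for e in self.entities],
            ui=[u.copy() for u in self.ui],
        )


@dataclass(frozen=True)
class ValidationIssue:
    severity: str   # error | warning
    code: str       # stable machine code from errors.CODES
    locus: str      # path into the model, e.g. "entity:Sample/field:Experiment"
    message: str

    def __str__(self) -> str:
        return f"{self.severity.upper()} {self.code} at {self.locus}: {self.message}"
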