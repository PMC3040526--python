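"""Relational DDL generation: one table per entity.

Column types follow a fixed mapping, NOT NULL mirrors ``nillable=false``,
UNIQUE mirrors ``unique=true`` and every xref becomes a FOREIGN KEY.  Tables
are emitted in entity load order so referenced tables exist before their
referrers.  The single target dialect is the embedded SQLite engine;
``readonly`` is a data-layer concern and does not appear in DDL.
"""

from __future__ import annotations

from .dsl import entity_load_order
from .errors import ModelError
from .model import UNSET, Entity, Field, Model

#: DSL type -> DDL type pattern ({n} = max_length).
SQL_TYPES = {
    "string": "VARCHAR({n})",
    "text": "TEXT",
    "int": "INTEGER",
    "decimal": "DOUBLE PRECISION",
    "bool": "BOOLEAN",
    "date": "DATE",
}


def sql_type(field: Field, model: Model | None = None) -> str:
    """The DDL type of *field*.

    An xref column takes the SQL type of the referenced field, which requires
    *model*; chains (an xref targeting another xref) are unsupported.
    """
    if field.type == "xref":
        if model is None:
            raise ModelError("SCHEMA_XREF_CHAIN",
                             f"resolving xref field {field.name!r} requires the model")
        target_entity = model.entity(field.xref_entity)  # type: ignore[arg-type]
        if target_entity is None:
            raise ModelError("XREF_TARGET_MISSING",
                             f"xref field {field.name!r} targets unknown entity "
                             f"{field.xref_entity!r}")
        target = target_entity.field(field.xref_field)  # type: ignore[arg-type]
        if target is None:
            raise ModelError("XREF_TARGET_MISSING",
                             f"xref field {field.name!r} targets unknown field "
                             f"{field.xref_entity}.{field.xref_field}")
        if target.type == "xref":
            raise ModelError(
                "SCHEMA_XREF_CHAIN",
                f"xref field {field.name!r} targets xref field "
                f"{field.xref_entity}.{field.xref_field}; chains are unsupported")
        return sql_type(target)
    pattern = SQL_TYPES[field.type]  # type: ignore[index]
    if field.type == "string":
        length = field.max_length if isinstance(field.max_length, int) else 255
        return pattern.format(n=length)
    return pattern


def sql_type_name(field: Field) -> str:
    """Like :func:`sql_type` but usable without the model (template command):
    xref columns report the generic key type ``VARCHAR(255)`` when the target
    is unavailable."""
    if field.type == "xref":
        return "VARCHAR(255)"
    return sql_type(field)


def create_table_ddl(entity: Entity, model: Model | None = None) -> str:
    """One CREATE TABLE statement for a flattened entity.

    Column order is model order; NOT NULL iff not nillable, UNIQUE iff
    unique, one FOREIGN KEY clause per xref field.
    """
    columns: list[str] = []
    foreign_keys: list[str] = []
    for f in entity.fields:
        parts = [f'"{f.name}"', sql_type(f, model)]
        if f.nillable is not True:
            parts.append("NOT NULL")
        if f.unique is True:
            parts.append("UNIQUE")
        columns.append("  " + " ".join(parts))
        if f.type == "xref":
            foreign_keys.append(
                f'  FOREIGN KEY ("{f.name}") REFERENCES '
                f'"{f.xref_entity}" ("{f.xref_field}")')
    body = ",\n".join(columns + foreign_keys)
    return f'CREATE TABLE "{entity.name}" (\n{body}\n);'


def schema_ddl(model: Model) -> str:
    """The full DDL script for a validated model, referenced tables first."""
    order = entity_load_order(model)
    statements = []
    for name in order:
        entity = model.entity(name)
        assert entity is not None
        statements.append(create_table_ddl(entity, model))
    return "\n\n".join(statements) + ("\n" if statements else "")
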