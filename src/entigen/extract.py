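"""Reverse-engineer a model from an existing relational schema.

``introspect`` captures tables, columns, constraints and foreign keys from a
live SQLite database, a database file, or a DDL script; ``to_model`` inverts
the schema generator's mapping (table -> entity, NOT NULL -> required,
UNIQUE -> unique, FK -> xref) and emits a skeleton UI (one list form per
entity) so the generated application is immediately usable.

Extraction is lossy by design: labels, descriptions, readonly flags, the
inheritance structure and the original UI cannot be recovered from DDL.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .errors import ExtractError
from .model import UNSET, Entity, Field, Model, UIElement, ValidationIssue


@dataclass(frozen=True)
class Column:
    name: str
    sql_type: str       # raw type text as stored in the schema
    not_null: bool
    unique: bool


@dataclass(frozen=True)
class ForeignKey:
    columns: tuple[str, ...]
    target_table: str
    target_columns: tuple[str, ...]


@dataclass
class Table:
    name: str
    columns: list[Column] = dc_field(default_factory=list)
    foreign_keys: list[ForeignKey] = dc_field(default_factory=list)


@dataclass
class IntrospectedSchema:
    tables: list[Table] = dc_field(default_factory=list)


def introspect(db) -> IntrospectedSchema:
    """Capture the structure of *db*.

    *db* may be an open ``sqlite3.Connection``, a path to a database file, a
    path to a ``.sql`` DDL script, or DDL text itself.
    """
    conn, close = _open(db)
    try:
        schema = IntrospectedSchema()
        tables = [r[0] for r in conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name NOT LIKE 'sqlite_%' ORDER BY rowid")]
        for table_name in tables:
            table = Table(name=table_name)
            unique_cols = _unique_columns(conn, table_name)
            for _, name, sql_type, not_null, _default, pk in conn.execute(
                    f'PRAGMA table_info("{table_name}")'):
                table.columns.append(Column(
                    name=name,
                    sql_type=sql_type or "",
                    not_null=bool(not_null) or pk == 1,
                    unique=name in unique_cols or pk == 1,
                ))
            fks: dict[int, list] = {}
            for row in conn.execute(f'PRAGMA foreign_key_list("{table_name}")'):
                fk_id, seq, target, col, target_col = row[0], row[1], row[2], row[3], row[4]
                fks.setdefault(fk_id, []).append((seq, col, target, target_col))
            for parts in fks.values():
                parts.sort()
                table.foreign_keys.append(ForeignKey(
                    columns=tuple(p[1] for p in parts),
                    target_table=parts[0][2],
                    target_columns=tuple(p[3] for p in parts),
                ))
            schema.tables.append(table)
        return schema
    finally:
        if close:
            conn.close()


def _open(db) -> tuple[sqlite3.Connection, bool]:
    if isinstance(db, sqlite3.Connection):
        return db, False
    if isinstance(db, Path) or (isinstance(db, str) and "\n" not in db
                                and Path(db).exists()):
        path = Path(db)
        if path.suffix.lower() == ".sql":
            return _from_ddl(path.read_text(encoding="utf-8")), True
        try:
            conn = sqlite3.connect(str(path))
            conn.execute("SELECT count(*) FROM sqlite_master")
            return conn, True
        except sqlite3.DatabaseError as exc:
            raise ExtractError("EXTRACT_IO_ERROR",
                               f"cannot read database {path}: {exc}") from None
    if isinstance(db, str):
        return _from_ddl(db), True
    raise ExtractError("EXTRACT_IO_ERROR",
                       f"unsupported introspection input {type(db).__name__}")


def _from_ddl(ddl: str) -> sqlite3.Connection:
    conn = sqlite3.connect(":memory:")
    try:
        conn.executescript(ddl)
    except sqlite3.Error as exc:
        conn.close()
        raise ExtractError("EXTRACT_IO_ERROR",
                           f"DDL script does not execute: {exc}") from None
    return conn


def _unique_columns(conn: sqlite3.Connection, table: str) -> set[str]:
    """Columns covered by a single-column unique index or constraint."""
    out: set[str] = set()
    for row in conn.execute(f'PRAGMA index_list("{table}")'):
        index_name, is_unique = row[1], row[2]
        if not is_unique:
            continue
        cols = [r[2] for r in conn.execute(f'PRAGMA index_info("{index_name}")')]
        if len(cols) == 1 and cols[0] is not None:
            out.add(cols[0])
    return out


# -- inverse type mapping ----------------------------------------------------

_VARCHAR = re.compile(r"^\s*(?:VAR)?CHAR(?:ACTER)?\s*\(\s*(\d+)\s*\)\s*$", re.I)
_SIMPLE = {
    "TEXT": "text",
    "CLOB": "text",
    "INTEGER": "int",
    "INT": "int",
    "BIGINT": "int",
    "SMALLINT": "int",
    "DOUBLE PRECISION": "decimal",
    "DOUBLE": "decimal",
    "REAL": "decimal",
    "FLOAT": "decimal",
    "NUMERIC": "decimal",
    "DECIMAL": "decimal",
    "BOOLEAN": "bool",
    "BOOL": "bool",
    "DATE": "date",
}


def _map_type(raw: str) -> tuple[str, int | None, bool]:
    """raw SQL type -> (dsl type, max_length, mapped?)."""
    match = _VARCHAR.match(raw)
    if match:
        return "string", int(match.group(1)), True
    key = re.sub(r"\s+", " ", raw.strip().upper())
    if key in _SIMPLE:
        return _SIMPLE[key], None, True
    return "string", 255, False


def to_model(schema: IntrospectedSchema,
             name: str = "extracted") -> tuple[Model, list[ValidationIssue]]:
    """Build a model from an introspected schema, degrading to warnings.

    Unmapped column types become ``string`` fields; composite foreign keys
    are imported as plain columns; a foreign key onto a non-unique column
    promotes the target to unique.  The returned model always passes
    validation.
    """
    warnings: list[ValidationIssue] = []
    model = Model(name=name)
    by_table = {t.name.lower(): t for t in schema.tables}

    for table in schema.tables:
        entity = Entity(name=table.name)
        fk_by_column: dict[str, ForeignKey] = {}
        for fk in table.foreign_keys:
            locus = f"entity:{table.name}"
            if len(fk.columns) != 1:
                warnings.append(ValidationIssue(
                    "warning", "EXTRACT_COMPOSITE_FK", locus,
                    f"composite foreign key {fk.columns} -> "
                    f"{fk.target_table}{fk.target_columns} imported as plain "
                    f"fields"))
                continue
            if fk.target_table.lower() not in by_table:
                warnings.append(ValidationIssue(
                    "warning", "EXTRACT_COMPOSITE_FK", locus,
                    f"foreign key {fk.columns[0]} -> missing table "
                    f"{fk.target_table!r} imported as a plain field"))
                continue
            fk_by_column[fk.columns[0].lower()] = fk

        for column in table.columns:
            locus = f"entity:{table.name}/field:{column.name}"
            fk = fk_by_column.get(column.name.lower())
            if fk is not None:
                field = Field(
                    name=column.name,
                    type="xref",
                    xref_entity=fk.target_table,
                    xref_field=fk.target_columns[0]
                    if fk.target_columns and fk.target_columns[0]
                    else "rowid",
                    nillable=not column.not_null,
                    unique=column.unique,
                    defined_in=table.name,
                )
            else:
                dsl_type, max_length, mapped = _map_type(column.sql_type)
                if not mapped:
                    warnings.append(ValidationIssue(
                        "warning", "EXTRACT_UNMAPPED_TYPE", locus,
                        f"column type {column.sql_type!r} has no DSL "
                        f"equivalent; imported as string"))
                field = Field(
                    name=column.name,
                    type=dsl_type,
                    max_length=max_length if max_length is not None else UNSET,
                    nillable=not column.not_null,
                    unique=column.unique,
                    defined_in=table.name,
                )
            entity.fields.append(field)
        model.entities.append(entity)

    # promote non-unique foreign-key targets so the model validates
    for table in schema.tables:
        for fk in table.foreign_keys:
            if len(fk.columns) != 1:
                continue
            target = model.entity(fk.target_table)
            if target is None:
                continue
            tcol = fk.target_columns[0] if fk.target_columns else None
            tfield = target.field(tcol) if tcol else None
            if tfield is not None and tfield.unique is not True:
                warnings.append(ValidationIssue(
                    "warning", "EXTRACT_FK_NOT_UNIQUE",
                    f"entity:{target.name}/field:{tfield.name}",
                    f"foreign-key target {target.name}.{tfield.name} was not "
                    f"unique in the schema; promoted to unique"))
                tfield.unique = True

    # skeleton UI so the generated application is usable out of the box
    for entity in model.entities:
        model.ui.append(UIElement(kind="form", name=entity.name,
                                  entity=entity.name, view_mode="list"))
    return model, warnings


def model_core_signature(model: Model):
    """The structural core of a model that survives the schema round trip.

    Lossy aspects (UI, labels, descriptions, readonly flags, inheritance
    markers, default values, entity order) are excluded; fields appear in
    flattened order.
    """
    from .dsl import apply_defaults, resolve_inheritance

    normalized = resolve_inheritance(apply_defaults(model))
    entities = []
    for entity in sorted(normalized.entities, key=lambda e: e.name.lower()):
        fields = tuple(
            (f.name, f.type,
             f.max_length if isinstance(f.max_length, int) else None,
             bool(f.nillable is True), bool(f.unique is True),
             f.xref_entity.lower() if isinstance(f.xref_entity, str) else None,
             f.xref_field.lower() if isinstance(f.xref_field, str) else None)
            for f in entity.fields)
        entities.append((entity.name.lower(), fields))
    return tuple(entities)
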