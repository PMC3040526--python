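"""Runtime data layer: a model-aware store on the embedded SQLite engine.

The store enforces the model's semantics beyond what DDL can express —
readonly fields, friendly error codes for nillable/unique/xref violations,
and referential blocking of deletes — and exposes the classic operation set:
add, update, remove, find (filter + sort + page) and count.
"""

from __future__ import annotations

import datetime as dt
import sqlite3
from dataclasses import dataclass
from typing import Any, Optional

from .errors import StoreError
from .model import Entity, Field, Model
from .schema import schema_ddl

FILTER_OPS = ("equals", "like", "lt", "le", "gt", "ge")
_SQL_OPS = {"equals": "=", "lt": "<", "le": "<=", "gt": ">", "ge": ">="}

#: Hard ceiling on page size.
MAX_PAGE_LIMIT = 1000


@dataclass(frozen=True)
class Filter:
    field: str
    op: str     # equals | like | lt | le | gt | ge
    value: Any


@dataclass(frozen=True)
class Page:
    offset: int = 0
    limit: int = MAX_PAGE_LIMIT

    def __post_init__(self):
        if self.offset < 0 or self.limit < 1 or self.limit > MAX_PAGE_LIMIT:
            raise ValueError(f"invalid page {self!r} (limit must be in "
                             f"1..{MAX_PAGE_LIMIT}, offset >= 0)")

    # "first / previous / next / last" navigation is offset arithmetic:
    def first(self) -> "Page":
        return Page(0, self.limit)

    def previous(self) -> "Page":
        return Page(max(0, self.offset - self.limit), self.limit)

    def next(self) -> "Page":
        return Page(self.offset + self.limit, self.limit)

    def last(self, total: int) -> "Page":
        if total <= self.limit:
            return Page(0, self.limit)
        remainder = total % self.limit
        return Page(total - (remainder or self.limit), self.limit)


def parse_value(field: Field, text: str | None):
    """Convert a text cell to the field's python value; empty/None means NULL."""
    if text is None or text == "":
        return None
    t = field.type
    try:
        if t == "int":
            return int(text)
        if t == "decimal":
            return float(text)
        if t == "bool":
            low = text.strip().lower()
            if low in ("true", "1"):
                return True
            if low in ("false", "0"):
                return False
            raise ValueError(text)
        if t == "date":
            return dt.date.fromisoformat(text.strip()).isoformat()
        return text
    except ValueError:
        raise StoreError("TYPE_INVALID",
                         f"value {text!r} is not a valid {t}") from None


def format_value(field: Field, value) -> str:
    """Inverse of :func:`parse_value` for export; NULL encodes as empty."""
    if value is None:
        return ""
    if field.type == "bool":
        return "true" if value else "false"
    if field.type == "decimal":
        return repr(float(value))
    return str(value)


class Store:
    """One application database bound to its compiled model."""

    def __init__(self, model: Model, path: str = ":memory:",
                 create: bool = True):
        self.model = model
        self.conn = sqlite3.connect(path)
        self.conn.execute("PRAGMA foreign_keys = ON")
        if create:
            existing = {r[0] for r in self.conn.execute(
                "SELECT name FROM sqlite_master WHERE type='table'")}
            if not existing:
                self.conn.executescript(schema_ddl(model))
                self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    # -- helpers ------------------------------------------------------------

    def _entity(self, name: str) -> Entity:
        entity = self.model.entity(name)
        if entity is None:
            raise StoreError("ENTITY_UNKNOWN", f"unknown entity {name!r}")
        return entity

    def _key(self, entity: Entity) -> Field:
        key = entity.key_field()
        if key is None:
            raise StoreError("ENTITY_UNKNOWN",
                             f"entity {entity.name!r} has no unique key field")
        return key

    def _check_fields(self, entity: Entity, record: dict) -> None:
        for name in record:
            if entity.field(name) is None:
                raise StoreError(
                    "QUERY_UNKNOWN_FIELD",
                    f"entity {entity.name!r} has no field {name!r}")

    def _check_xref(self, field: Field, value) -> None:
        if value is None:
            return
        row = self.conn.execute(
            f'SELECT 1 FROM "{field.xref_entity}" WHERE "{field.xref_field}" = ?',
            (value,)).fetchone()
        if row is None:
            raise StoreError(
                "XREF_UNRESOLVED",
                f"no {field.xref_entity} row with {field.xref_field} = {value!r}")

    def _to_sql(self, value):
        if isinstance(value, bool):
            return int(value)
        return value

    def _from_sql(self, field: Field, value):
        if value is None:
            return None
        if field.type == "bool":
            return bool(value)
        return value

    def _row_to_record(self, entity: Entity, row) -> dict:
        return {f.name: self._from_sql(f, v) for f, v in zip(entity.fields, row)}

    def _select_cols(self, entity: Entity) -> str:
        return ", ".join(f'"{f.name}"' for f in entity.fields)

    # -- CRUD ---------------------------------------------------------------

    def add(self, entity_name: str, record: dict) -> dict:
        """Insert one record; returns it as stored."""
        entity = self._entity(entity_name)
        self._check_fields(entity, record)
        values: dict[str, Any] = {}
        for f in entity.fields:
            value = record.get(f.name)
            if value is None and f.default_value not in (None,) and \
                    isinstance(f.default_value, str):
                value = parse_value(f, f.default_value)
            if value is None and f.nillable is not True:
                raise StoreError(
                    "NOT_NILLABLE",
                    f"field {entity.name}.{f.name} is required")
            if f.type == "xref":
                self._check_xref(f, value)
            if f.unique is True and value is not None:
                dup = self.conn.execute(
                    f'SELECT 1 FROM "{entity.name}" WHERE "{f.name}" = ?',
                    (self._to_sql(value),)).fetchone()
                if dup is not None:
                    raise StoreError(
                        "DUPLICATE_KEY",
                        f"duplicate value {value!r} for unique field "
                        f"{entity.name}.{f.name}")
            values[f.name] = value
        cols = ", ".join(f'"{n}"' for n in values)
        marks = ", ".join("?" for _ in values)
        self.conn.execute(
            f'INSERT INTO "{entity.name}" ({cols}) VALUES ({marks})',
            [self._to_sql(v) for v in values.values()])
        self.conn.commit()
        key = self._key(entity)
        return self.get(entity_name, values[key.name])

    def get(self, entity_name: str, key_value) -> dict:
        entity = self._entity(entity_name)
        key = self._key(entity)
        row = self.conn.execute(
            f'SELECT {self._select_cols(entity)} FROM "{entity.name}" '
            f'WHERE "{key.name}" = ?', (self._to_sql(key_value),)).fetchone()
        if row is None:
            raise StoreError("NOT_FOUND",
                             f"no {entity.name} row with {key.name} = {key_value!r}")
        return self._row_to_record(entity, row)

    def _where(self, entity: Entity, filters: list[Filter]):
        clauses: list[str] = []
        params: list[Any] = []
        for flt in filters:
            field = entity.field(flt.field)
            if field is None:
                raise StoreError(
                    "QUERY_UNKNOWN_FIELD",
                    f"entity {entity.name!r} has no field {flt.field!r}")
            if flt.op not in FILTER_OPS:
                raise StoreError("QUERY_BAD_OPERATOR",
                                 f"unknown filter operator {flt.op!r}")
            if flt.op == "like":
                if field.type not in ("string", "text"):
                    raise StoreError(
                        "QUERY_BAD_OPERATOR",
                        f"'like' applies to string/text fields, not "
                        f"{field.type}")
                clauses.append(f'"{field.name}" LIKE ? ESCAPE \'\\\'')
                escaped = str(flt.value).replace("\\", "\\\\") \
                    .replace("%", "\\%").replace("_", "\\_")
                params.append(f"%{escaped}%")
            else:
                clauses.append(f'"{field.name}" {_SQL_OPS[flt.op]} ?')
                params.append(self._to_sql(flt.value))
        where = (" WHERE " + " AND ".join(clauses)) if clauses else ""
        return where, params

    def find(self, entity_name: str, filters: list[Filter] | None = None,
             page: Page | None = None,
             sort: Optional[str] = None) -> tuple[list[dict], int]:
        """Records matching the conjunction of *filters*, plus the unpaged
        total.  Deterministic order: *sort* field (when given) then key."""
        entity = self._entity(entity_name)
        filters = filters or []
        page = page or Page()
        where, params = self._where(entity, filters)
        key = self._key(entity)
        order_cols = []
        if sort is not None:
            if entity.field(sort) is None:
                raise StoreError("QUERY_UNKNOWN_FIELD",
                                 f"entity {entity.name!r} has no field {sort!r}")
            order_cols.append(f'"{entity.field(sort).name}"')
        order_cols.append(f'"{key.name}"')
        total = self.conn.execute(
            f'SELECT COUNT(*) FROM "{entity.name}"{where}', params).fetchone()[0]
        rows = self.conn.execute(
            f'SELECT {self._select_cols(entity)} FROM "{entity.name}"{where} '
            f'ORDER BY {", ".join(order_cols)} LIMIT ? OFFSET ?',
            params + [page.limit, page.offset]).fetchall()
        return [self._row_to_record(entity, r) for r in rows], total

    def count(self, entity_name: str,
              filters: list[Filter] | None = None) -> int:
        entity = self._entity(entity_name)
        where, params = self._where(entity, filters or [])
        return self.conn.execute(
            f'SELECT COUNT(*) FROM "{entity.name}"{where}', params).fetchone()[0]

    def update(self, entity_name: str, key_value, changes: dict) -> dict:
        """Apply *changes* to the row with the given key; readonly fields may
        not change."""
        entity = self._entity(entity_name)
        self._check_fields(entity, changes)
        current = self.get(entity_name, key_value)  # raises NOT_FOUND
        effective: dict[str, Any] = {}
        for name, value in changes.items():
            field = entity.field(name)
            assert field is not None
            if field.readonly is True and value != current[field.name]:
                raise StoreError(
                    "READONLY_VIOLATION",
                    f"field {entity.name}.{field.name} is read-only")
            if value is None and field.nillable is not True:
                raise StoreError("NOT_NILLABLE",
                                 f"field {entity.name}.{field.name} is required")
            if field.type == "xref":
                self._check_xref(field, value)
            if field.unique is True and value is not None \
                    and value != current[field.name]:
                dup = self.conn.execute(
                    f'SELECT 1 FROM "{entity.name}" WHERE "{field.name}" = ?',
                    (self._to_sql(value),)).fetchone()
                if dup is not None:
                    raise StoreError(
                        "DUPLICATE_KEY",
                        f"duplicate value {value!r} for unique field "
                        f"{entity.name}.{field.name}")
            effective[field.name] = value
        if effective:
            key = self._key(entity)
            sets = ", ".join(f'"{n}" = ?' for n in effective)
            self.conn.execute(
                f'UPDATE "{entity.name}" SET {sets} WHERE "{key.name}" = ?',
                [self._to_sql(v) for v in effective.values()]
                + [self._to_sql(key_value)])
            self.conn.commit()
        new_key = effective.get(self._key(entity).name, key_value)
        return self.get(entity_name, new_key)

    def remove(self, entity_name: str, key_value) -> int:
        """Delete the row with the given key; blocked while other rows
        reference it."""
        entity = self._entity(entity_name)
        key = self._key(entity)
        current = self.get(entity_name, key_value)  # raises NOT_FOUND
        for other in self.model.entities:
            for f in other.fields:
                if f.type == "xref" and isinstance(f.xref_entity, str) \
                        and f.xref_entity.lower() == entity.name.lower():
                    referenced = current.get(f.xref_field)
                    if referenced is None:
                        continue
                    sql = f'SELECT 1 FROM "{other.name}" WHERE "{f.name}" = ?'
                    params = [self._to_sql(referenced)]
                    if other.name.lower() == entity.name.lower():
                        # a row referencing itself does not block its removal
                        sql += f' AND "{key.name}" != ?'
                        params.append(self._to_sql(key_value))
                    hit = self.conn.execute(sql, params).fetchone()
                    if hit is not None:
                        raise StoreError(
                            "REFERENTIAL_BLOCK",
                            f"{other.name}.{f.name} still references "
                            f"{entity.name} {key_value!r}")
        cursor = self.conn.execute(
            f'DELETE FROM "{entity.name}" WHERE "{key.name}" = ?',
            (self._to_sql(key_value),))
        self.conn.commit()
        return cursor.rowcount
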