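"""Model-tailored tab-delimited import and export.

File dialect: UTF-8, tab separator, first line is the header and must name
model fields; CSV-style double-quote escaping applies when a cell contains a
tab, newline or quote.  An empty cell encodes NULL (the literal text "null"
is just text).  Cross-reference cells hold the referenced row's key value.

Batch import follows the model's entity load order; nillable cross-reference
edges that close a cycle are deferred to a second pass.  Import is row-atomic:
bad rows are reported, good rows are applied, so one pass over a large batch
surfaces every inconsistency.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from .dsl import entity_load_order
from .errors import StoreError
from .model import Entity, Model
from .store import Store, format_value, parse_value


class _Dialect(csv.Dialect):
    delimiter = "\t"
    quotechar = '"'
    doublequote = True
    lineterminator = "\n"
    quoting = csv.QUOTE_MINIMAL


@dataclass
class TabularFile:
    entity: str
    header: list[str]
    rows: list[list[str]] = dc_field(default_factory=list)

    def to_text(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, dialect=_Dialect)
        writer.writerow(self.header)
        writer.writerows(self.rows)
        return buf.getvalue()

    @classmethod
    def from_text(cls, entity: str, text: str) -> "TabularFile":
        reader = csv.reader(io.StringIO(text), dialect=_Dialect)
        rows = [row for row in reader]
        if not rows:
            raise StoreError("IMPORT_UNKNOWN_COLUMN",
                             f"file for entity {entity!r} has no header line")
        return cls(entity=entity, header=rows[0], rows=rows[1:])

    @classmethod
    def read(cls, path: str | Path, entity: str | None = None) -> "TabularFile":
        path = Path(path)
        name = entity if entity is not None else path.stem
        return cls.from_text(name, path.read_text(encoding="utf-8"))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text(), encoding="utf-8")


@dataclass(frozen=True)
class RowError:
    row: int        # 1-based data row number
    field: str
    code: str
    message: str


@dataclass
class ImportReport:
    entity: str
    rows_added: int = 0
    rows_updated: int = 0
    errors: list[RowError] = dc_field(default_factory=list)

    @property
    def rejected_rows(self) -> set[int]:
        return {e.row for e in self.errors}


def export_entity(store: Store, entity: Entity) -> TabularFile:
    """Dump one entity: header = all flattened field names in model order,
    rows sorted by the entity's key, NULL as empty cell."""
    key = entity.key_field()
    records, _ = store.find(entity.name, sort=key.name if key else None)
    header = [f.name for f in entity.fields]
    rows = [[format_value(f, record[f.name]) for f in entity.fields]
            for record in records]
    return TabularFile(entity=entity.name, header=header, rows=rows)


def _validate_header(entity: Entity, file: TabularFile) -> list:
    columns = []
    for name in file.header:
        field = entity.field(name)
        if field is None:
            raise StoreError(
                "IMPORT_UNKNOWN_COLUMN",
                f"header column {name!r} matches no field of entity "
                f"{entity.name!r}")
        columns.append(field)
    return columns


def import_file(store: Store, entity: Entity, file: TabularFile,
                mode: str = "add_update",
                defer_fields: set[str] | None = None,
                deferred_out: list | None = None) -> ImportReport:
    """Load one tabular file into the store.

    mode ``add`` always inserts, ``update`` requires the key to exist,
    ``add_update`` (default) upserts on the entity's key field.  Rows are
    independent: a bad row is reported and skipped while the rest commit.

    *defer_fields* names xref fields whose resolution is postponed (cycle
    edges); their cell values are loaded as NULL and recorded in
    *deferred_out* as ``(entity, key, field, value, row)`` for a second pass.
    """
    if mode not in ("add", "update", "add_update"):
        raise ValueError(f"unknown import mode {mode!r}")
    columns = _validate_header(entity, file)
    defer_fields = {n.lower() for n in (defer_fields or set())}
    key = entity.key_field()
    report = ImportReport(entity=entity.name)
    seen_keys: set = set()

    for row_number, cells in enumerate(file.rows, start=1):
        if len(cells) != len(file.header):
            report.errors.append(RowError(
                row_number, "", "IMPORT_UNKNOWN_COLUMN",
                f"row has {len(cells)} cells, header has {len(file.header)}"))
            continue
        try:
            record = {}
            deferred_cells = []
            for field, cell in zip(columns, cells):
                value = parse_value(field, cell)
                if field.name.lower() in defer_fields and value is not None:
                    deferred_cells.append((field.name, value))
                    value = None
                record[field.name] = value
            key_value = record.get(key.name) if key is not None else None
            if key is not None and key_value is not None:
                if key_value in seen_keys:
                    raise StoreError(
                        "DUPLICATE_KEY",
                        f"key {key_value!r} appears twice in the file")
                seen_keys.add(key_value)
            exists = False
            if key is not None and key_value is not None:
                try:
                    store.get(entity.name, key_value)
                    exists = True
                except StoreError:
                    exists = False
            if mode == "add" or (mode == "add_update" and not exists):
                store.add(entity.name, record)
                report.rows_added += 1
            else:
                if not exists:
                    raise StoreError(
                        "NOT_FOUND",
                        f"update mode: no {entity.name} row with key "
                        f"{key_value!r}")
                changes = {n: v for n, v in record.items() if n != key.name}
                store.update(entity.name, key_value, changes)
                report.rows_updated += 1
            if deferred_out is not None:
                for field_name, value in deferred_cells:
                    deferred_out.append(
                        (entity.name, key_value, field_name, value, row_number))
        except StoreError as exc:
            bad_field = ""
            report.errors.append(RowError(row_number, bad_field, exc.code,
                                          exc.message))
    return report


def import_batch(store: Store, model: Model,
                 files: dict[str, TabularFile]) -> list[ImportReport]:
    """Import several files in entity load order.

    Nillable xref fields whose target entity comes later in the order (cycle
    edges, including self-references) are filled in a second pass once all
    rows exist.
    """
    order = entity_load_order(model)
    position = {name.lower(): i for i, name in enumerate(order)}
    for name in files:
        if model.entity(name) is None:
            raise StoreError("IMPORT_UNKNOWN_ENTITY",
                             f"no entity {name!r} in the model")
    reports: list[ImportReport] = []
    deferred: list[tuple] = []
    by_position = sorted(files, key=lambda n: position[model.entity(n).name.lower()])
    report_by_entity: dict[str, ImportReport] = {}
    for name in by_position:
        entity = model.entity(name)
        assert entity is not None
        defer = set()
        for f in entity.fields:
            if f.type == "xref" and isinstance(f.xref_entity, str):
                target_low = f.xref_entity.lower()
                if target_low == entity.name.lower() or \
                        position[target_low] > position[entity.name.lower()]:
                    defer.add(f.name)
        report = import_file(store, entity, files[name],
                             defer_fields=defer, deferred_out=deferred)
        reports.append(report)
        report_by_entity[entity.name] = report

    for entity_name, key_value, field_name, value, row_number in deferred:
        report = report_by_entity[entity_name]
        try:
            store.update(entity_name, key_value, {field_name: value})
        except StoreError as exc:
            # the row cannot keep its half-loaded state: retract it
            try:
                store.remove(entity_name, key_value)
                report.rows_added -= 1
            except StoreError:
                pass
            report.errors.append(RowError(row_number, field_name, exc.code,
                                          exc.message))
    return reports
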