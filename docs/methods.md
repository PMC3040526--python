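# Methods

This note documents the modeling language's semantics, the conventions and
numerical choices the toolkit fixes where a design was genuinely open, what
the synthetic fixtures do and do not emulate, and known limitations.

## The modeling language

A model is one XML document: `<molgenis name>` containing `<entity>` and
`<ui>` sections. The vocabulary is deliberately small:

| element | attributes |
|---|---|
| `entity` | `name`, `label`, `description`, `extends` |
| `field`  | `name`, `type`, `nillable`, `readonly`, `unique`, `length`, `xref_entity`, `xref_field`, `label`, `description`, `default` |
| `form`   | `name`, `entity`, `view` (`record`/`list`), `link` |
| `menu`   | `name` |
| `plugin` | `name`, `id` |

Field types are `string`, `text`, `int`, `decimal`, `bool`, `date`, `xref`.
The paper-style core is string (variable characters, length 255), decimal
and xref; `text`, `int`, `bool` and `date` are documented extensions chosen
because laboratory tables invariably need them. Many-to-many references
(`mref`) are deliberately out of scope.

**Convention over configuration.** Parsing preserves "unset" as a distinct
state; `apply_defaults` then fills conventions — type `string`, length 255,
required, editable, not unique, label = name, record-per-screen forms. The
two-stage design keeps defaulting idempotent and lets the serializer emit a
canonical minimal form (attributes equal to their default are omitted), so
`parse ∘ serialize` is the identity on normalized models.

**Keys and cross-references.** There are no implicit surrogate keys: an
xref must target a field explicitly flagged `unique`, and an entity's row
identity is its first unique field in model order. This keeps exchange files
human-readable (xref cells hold the referenced key value, e.g. `E1`) at the
cost of requiring modelers to declare a key per entity. Xref chains (an xref
targeting another xref field) are rejected rather than flattened.

**Inheritance.** `extends` prepends the parent's flattened fields to the
child's, ancestor-first; redeclaring an inherited name is an error, as are
cycles. The marker is retained for documentation, and serialization emits
only fields an entity declares itself.

**Names** are matched case-insensitively everywhere (entities, fields, UI
siblings) but stored and emitted as declared.

**Cycles and load order.** Entities are ordered so every cross-referenced
entity precedes its referrers (Kahn's algorithm; ties broken by declaration
order, making the result the unique declaration-order-minimal topological
order — the property the brute-force permutation oracle in the test suite
checks). A cycle of non-nillable xrefs is a validation error since no load
order could satisfy it. A cycle with at least one nillable edge is legal:
the nillable edges inside the cyclic component are relaxed for ordering, and
batch import loads those cells as NULL, then fills them in a second pass
once all rows exist. Self-references must be nillable for the same reason.

**Strict vs lax parsing.** Unknown elements or attributes are errors by
default; a lax switch downgrades them to warnings collected on the model,
for tolerating files from newer dialect versions.

## Generators

Templates are text with `${command(args)}` holes. The command table —
`Name`, `name`, `label`, `type`, `sql_type`, and the mapper
`csv(list, command[, separator])` (separator defaults to `,`) — is the whole
language; there is deliberately no conditional or loop syntax beyond `csv`,
which keeps templates trivially analyzable and rendering pure. One uniform
`${...}` delimiter is used for every hole. Generated artifacts are
declarative (DDL, JSON manifests, markdown, DOT) and are executed or served
by the runtime modules, which makes generation byte-exactly verifiable; a
timestamp is added only on request (`stamp`), so regeneration over an
unchanged model is byte-identical. A manifest file records generated paths
and is used to delete them before the next run, so regeneration fully
replaces the previous output.

## Relational mapping

One table per entity (flattened), columns in model order. Type mapping:
string → `VARCHAR(n)`, text → `TEXT`, int → `INTEGER`, decimal →
`DOUBLE PRECISION`, bool → `BOOLEAN`, date → `DATE`; an xref column takes
the SQL type of its target field. `NOT NULL` iff not nillable, `UNIQUE` iff
unique, one `FOREIGN KEY` per xref. The single target dialect is the
embedded SQLite engine (foreign keys enabled per connection); the mapping
table is a module-level constant and could be swapped per dialect, but no
other dialect is maintained. `readonly` is enforced in the data layer, not
in DDL, because SQL has no portable column-level immutability.

Dates are stored as ISO-8601 text and booleans as 0/1, the embedded
engine's conventions; the data layer converts at the boundary.

## Data exchange

Dialect: UTF-8, tab separator, first line = header, CSV-style double-quote
escaping when a cell contains a tab, newline or quote. An empty cell is
NULL; the literal string `null` is just text. The default import mode is
`add_update` (upsert on the entity's key), matching routine data-management
use; `add` and `update` are available. Import is row-atomic rather than
file-atomic so one pass over a large batch reports every inconsistent row
instead of stopping at the first. The per-file report satisfies
rows_added + rows_updated + rejected rows = input rows; if a deferred
cycle edge cannot be resolved in the second pass, the half-loaded row is
retracted so the report stays truthful.

## Query layer and REST contract

Filters are conjunctive only (`equals`, `like`, `lt`, `le`, `gt`, `ge`);
`like` means case-insensitive substring containment and applies to
string/text fields. Result order is the sort field then the key, so paging
is deterministic; first/previous/next/last navigation is offset arithmetic
on the client's `Page`, not server state. The page limit ceiling is 1000
rows. The REST dialect (paths `/api/v1/{entity}` with entity names
lower-cased, `_offset`/`_limit`/`_sort` parameters, the
`{"items", "total", "offset", "limit"}` envelope, error bodies
`{"code", "message"}`) is a local contract; field names appear in JSON
verbatim. Each UI `plugin` declaration becomes a named extension point
mounted at `/plugin/{id}` where an operator registers a handler at runtime;
no plugin is shipped.

## Reverse engineering

`introspect` captures tables, columns, single-column unique
indexes/constraints and foreign keys; `to_model` inverts the relational
mapping. Extraction is lossy by design: labels, descriptions, readonly
flags, inheritance structure, default values and the original UI are not
recoverable from DDL, so the round-trip guarantee is equality of the
structural core (entities as a set, flattened fields with types, lengths,
nillable/unique flags and xref targets). Degradations are warnings, never
errors: unmapped column types import as `string`, composite foreign keys as
plain columns, and a foreign key onto a non-unique column promotes the
target to unique so the extracted model always validates. A skeleton UI
(one list form per entity) is emitted so the generated application is
immediately usable.

## Synthetic fixtures

`random_model` emulates the shape of laboratory information models: one
unique string key per entity, 1–5 typed attribute fields drawn from a
genetics/phenotyping vocabulary, xrefs only toward earlier entities (so
generated models are acyclic by construction), occasional inheritance, and
a form/sub-form UI. Defect injection (`xref_missing`, `cycle`, `dup_field`,
`bad_header`) produces exactly one class of invalidity for negative tests.
`random_data` generates type-conforming values with ~20 % NULLs in nillable
fields and xref cells drawn from generated target keys. The fixtures do not
emulate: realistic biological value distributions, very wide tables,
Unicode-heavy identifiers, concurrent writers, or dirty real-world
spreadsheets (ragged rows, locale number formats); passing tests therefore
demonstrate structural and semantic correctness of the pipeline, not
robustness to arbitrary field data.

Test and acceptance problem sizes — models of 2–7 entities (the range a
permutation oracle can enumerate), 50–100 random models per suite, 6–20
rows per entity — are chosen so each property is exercised across many
structures; all randomness is seed-derived and reproducible.

## Known limitations

- Single SQL dialect; no schema migration between model versions.
- No security layer (users/roles), no HTML GUI, no SOAP/RDF interfaces.
- Only direct xref links connect child forms to parents (no multi-hop).
- No `mref`, no ontology annotation, no modular model includes.
- The REST service is single-process; the stdlib WSGI server is meant for
  local use, not production deployment.
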