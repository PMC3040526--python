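# entigen

A model-driven generator toolkit for biological research data management.

Research groups that run experiments — microarray studies, genotype/phenotype
collections, biobanks — need bespoke data-management software: a database
whose tables match *their* entities, screens organized around *their*
workflow, and an exchange format *their* spreadsheets can feed. Writing that
software by hand is slow and repetitive. entigen takes the model-driven
route: you declare the entities, their typed fields, cross-references and
screens in one compact XML file, and a generator suite turns that model into
a working application — relational schema, CRUD/REST service, tab-delimited
import/export tailored to the model, documentation and an
entity-relationship graph. When the science changes, you change the model
and regenerate.

## The method

**Modeling language.** One XML document declares data *entities* with typed
*fields* and a declarative user interface of *forms*, *menus* and *plugins*.
Unset attributes get convention-over-configuration defaults: a field is a
`string` of length 255, required (not *nillable*), editable (not *readonly*)
and not unique, unless declared otherwise. A field of type `xref` holds the
key of a row in another entity — the relational foreign key, raised to the
model level. Entities may inherit (`extends`), and a child form is
automatically linked to its parent form through the xref connecting their
entities.

**Generators.** Each generator is a plain-text template whose variable parts
are *holes* `${...}` filled per model element — `${Name(entity)}` becomes
`Experiment`, `${csv(entity.fields, name)}` maps a command over the field
list and joins with commas. The orchestrator renders every generator over
the model into an application directory: `schema.sql`, a REST route
manifest, a UI layout descriptor, per-entity data mappers, docs and an ER
graph. Generation is a pure function of the model, so regeneration is
byte-identical and fully replaces earlier output.

**Runtime.** The generated schema runs on the embedded SQLite engine. A
model-aware data layer provides add / update / remove / find / count with
conjunctive filters, sorting and offset pagination, enforcing nillable,
unique, readonly and referential rules with stable error codes; a WSGI
REST/JSON service exposes it per entity. Tab-delimited files whose header
row names model fields can be batch-imported in dependency (load) order,
row-atomically, with a structured report per file.

**ExtractModel.** The reverse path: introspect an existing relational
database (or DDL script) and recover a model — tables become entities,
`NOT NULL`/`UNIQUE` constraints become field flags, foreign keys become
xrefs — so a legacy database gains generated interfaces.

## Worked example

The bundled example models a microbial stress-experiment lab: entities
`Experiment`, `Sample` and `Hybridization`, where `Sample.Experiment` and
`Hybridization.Sample` are xrefs, and the UI shows one experiment per screen
with sub-forms listing its samples and hybridizations.

```python
import entigen as eg
from entigen.store import Store, Filter

model = eg.compile_model(eg.EXAMPLE_MODEL_XML)
print("entities:", ", ".join(e.name for e in model.entities))
print("load order:", " -> ".join(eg.entity_load_order(model)))

store = Store(model)                       # in-memory application database
store.add("Experiment", {"ID": "E1", "Name": "heat shock",
                         "Medium": "glucose", "Stress": "heat",
                         "Temperature": 30.0})
store.add("Sample", {"ID": "S1", "Experiment": "E1", "Tissue": "culture"})
records, total = store.find("Sample", [Filter("Experiment", "equals", "E1")])
print("samples of E1:", total, records[0]["ID"])

file = eg.export_entity(store, model.entity("Sample"))
print(file.to_text())
```

prints

```
entities: Experiment, Sample, Hybridization
load order: Experiment -> Sample -> Hybridization
samples of E1: 1 S1
ID	Experiment	Tissue	Protocol
S1	E1	culture
```

The load order says referenced entities are created and populated before
their referrers; the find call returns the one sample filed under experiment
`E1` together with the unpaged total; the export is the model-tailored
tab-delimited format (empty cell = NULL) whose headers match the model's
field names — the same format `entigen import` accepts.

The same flows are available from the shell:

```sh
entigen generate --model model.xml --out app/     # schema, routes, ui, docs
entigen import   --model model.xml --db app.db --dir data/
entigen export   --model model.xml --db app.db --entity Experiment
entigen serve    --model model.xml --db app.db --port 8080
entigen extract  --db legacy.db --out model.xml   # reverse engineering
entigen fixtures --seed 1 --entities 4 --out fx/  # synthetic demo data
```

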