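"""Synthetic models and datasets for testing and demonstration.

``random_model`` produces valid models (acyclic cross-references, one unique
key per entity) from a seed, with optional injected defects for negative
tests; ``random_data`` produces conforming tab-delimited files for any valid
model.  Entity and field names are drawn from a molecular-genetics
vocabulary so fixtures read like the laboratory information systems the
toolkit targets.  Value distributions make no claim of biological realism.

``EXAMPLE_MODEL_XML`` is the worked example used throughout the
documentation: a microbe stress-experiment database with Experiment, Sample
and Hybridization entities and a form/sub-form user interface.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .dsl import entity_load_order
from .exchange import TabularFile
from .model import UNSET, Entity, Field, Model, UIElement

EXAMPLE_MODEL_XML = """\
<molgenis name="microbe_experiments">
  <entity name="Experiment" description="A microbial stress experiment">
    <field name="ID" unique="true" readonly="true"/>
    <field name="Name"/>
    <field name="Medium"/>
    <field name="Stress"/>
    <field name="Temperature" type="decimal" nillable="true"/>
    <field name="StartDate" type="date" nillable="true"/>
  </entity>
  <entity name="Sample" description="A biomaterial taken in an experiment">
    <field name="ID" unique="true" readonly="true"/>
    <field name="Experiment" type="xref" xref_entity="Experiment" xref_field="ID"/>
    <field name="Tissue" nillable="true"/>
    <field name="Protocol" nillable="true"/>
  </entity>
  <entity name="Hybridization" description="A labeled sample on an array">
    <field name="ID" unique="true" readonly="true"/>
    <field name="Experiment" type="xref" xref_entity="Experiment" xref_field="ID"/>
    <field name="Sample" type="xref" xref_entity="Sample" xref_field="ID"/>
    <field name="Dye" nillable="true"/>
  </entity>
  <ui>
    <plugin name="header" id="app_header"/>
    <form name="Experiments" entity="Experiment">
      <menu name="Details">
        <form name="Samples" entity="Sample" view="list"/>
        <form name="Hybridizations" entity="Hybridization" view="list"/>
      </menu>
    </form>
  </ui>
</molgenis>
"""

_ENTITY_VOCAB = [
    "Experiment", "Sample", "Hybridization", "Marker", "Trait", "Subject",
    "Assay", "Protocol", "Probe", "Strain", "Panel", "Batch", "Phenotype",
    "Genotype", "Investigation", "Specimen",
]
_FIELD_VOCAB = [
    "Name", "Medium", "Stress", "Tissue", "Dye", "Unit", "Score", "Value",
    "Notes", "Count", "Weight", "Active", "Measured", "Chromosome",
    "Position", "Allele", "Sex", "Age", "Treatment", "Replicate",
]
_WORDS = ["glucose", "galactose", "heat", "cold", "oxidative", "control",
          "liver", "leaf", "root", "cy3", "cy5", "wildtype", "mutant"]

DEFECTS = ("xref_missing", "cycle", "dup_field", "bad_header")


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_entities: int = 4
    max_fields: int = 5
    xref_density: float = 0.6
    inherit_probability: float = 0.2
    defect: Optional[str] = None

    def __post_init__(self):
        if self.n_entities < 1 or self.max_fields < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.xref_density <= 1 and
                0 <= self.inherit_probability <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.defect is not None and self.defect not in DEFECTS:
            raise ValueError(f"unknown defect {self.defect!r}")


def _entity_name(i: int) -> str:
    base = _ENTITY_VOCAB[i % len(_ENTITY_VOCAB)]
    return base if i < len(_ENTITY_VOCAB) else f"{base}{i // len(_ENTITY_VOCAB) + 1}"


def random_model(spec: FixtureSpec) -> Model:
    """A reproducible model; valid unless a defect is requested."""
    rng = random.Random(spec.seed)
    model = Model(name=f"fixture_{spec.seed}")
    names = [_entity_name(i) for i in range(spec.n_entities)]

    for i, name in enumerate(names):
        entity = Entity(name=name)
        parent: Optional[Entity] = None
        if i > 0 and rng.random() < spec.inherit_probability:
            parent = model.entities[rng.randrange(i)]
            entity.extends = parent.name
        taken = set()
        scan = parent
        while scan is not None:
            taken.update(f.name.lower() for f in scan.fields)
            scan = model.entity(scan.extends) if isinstance(scan.extends, str) else None
        if parent is None:
            entity.fields.append(Field(name="ID", unique=True,
                                       defined_in=name))
            taken.add("id")
        candidates = [w for w in _FIELD_VOCAB if w.lower() not in taken]
        rng.shuffle(candidates)
        for field_name in candidates[:rng.randint(1, spec.max_fields)]:
            ftype = rng.choices(
                ["string", "text", "int", "decimal", "bool", "date"],
                weights=[5, 1, 2, 2, 1, 1])[0]
            entity.fields.append(Field(
                name=field_name,
                type=ftype if ftype != "string" or rng.random() < 0.3 else UNSET,
                nillable=True if rng.random() < 0.4 else UNSET,
                readonly=True if rng.random() < 0.1 else UNSET,
                max_length=rng.choice([32, 64, 255])
                if ftype == "string" and rng.random() < 0.3 else UNSET,
                defined_in=name,
            ))
            taken.add(field_name.lower())
        # acyclic by construction: only reference earlier entities
        if i > 0 and rng.random() < spec.xref_density:
            target = model.entities[rng.randrange(i)]
            ref_name = target.name if target.name.lower() not in taken \
                else f"{target.name}Ref"
            if ref_name.lower() not in taken:
                entity.fields.append(Field(
                    name=ref_name, type="xref",
                    xref_entity=target.name, xref_field="ID",
                    nillable=True if rng.random() < 0.3 else UNSET,
                    defined_in=name,
                ))
        model.entities.append(entity)

    _build_ui(model)
    if spec.defect is not None and spec.defect != "bad_header":
        _inject_defect(model, spec.defect, rng)
    return model


def _build_ui(model: Model) -> None:
    from .dsl import apply_defaults, resolve_inheritance

    model.ui.append(UIElement(kind="plugin", name="header", plugin_id="app_header"))
    root = model.entities[0]
    form = UIElement(kind="form", name=f"{root.name}Form", entity=root.name)
    menu = UIElement(kind="menu", name="Details")
    # child-form linking sees inherited fields too, so count on the
    # flattened entities
    flat = resolve_inheritance(apply_defaults(model))
    for entity in flat.entities[1:]:
        links = [f for f in entity.fields
                 if f.type == "xref" and f.xref_entity == root.name]
        if len(links) == 1:
            menu.children.append(UIElement(
                kind="form", name=f"{entity.name}List", entity=entity.name,
                view_mode="list"))
    if menu.children:
        form.children.append(menu)
    model.ui.append(form)


def _inject_defect(model: Model, defect: str, rng: random.Random) -> None:
    if defect == "xref_missing":
        xrefs = [f for e in model.entities for f in e.fields if f.type == "xref"]
        if xrefs:
            rng.choice(xrefs).xref_entity = "Nonexistent"
        else:
            model.entities[0].fields.append(Field(
                name="BrokenRef", type="xref",
                xref_entity="Nonexistent", xref_field="ID",
                defined_in=model.entities[0].name))
    elif defect == "cycle":
        if len(model.entities) < 2:  # pragma: no cover - spec guards sizes
            raise ValueError("cycle defect needs at least 2 entities")
        first, last = model.entities[0], model.entities[-1]
        # close a non-nillable loop against the existing earlier->later xrefs
        first.fields.append(Field(
            name=f"{last.name}Loop", type="xref",
            xref_entity=last.name, xref_field="ID", defined_in=first.name))
        if not any(f.type == "xref" and f.xref_entity == first.name
                   and f.nillable is not True for f in last.fields):
            last.fields.append(Field(
                name=f"{first.name}Loop", type="xref",
                xref_entity=first.name, xref_field="ID", defined_in=last.name))
    elif defect == "dup_field":
        entity = rng.choice(model.entities)
        entity.fields.append(entity.fields[-1].copy())


def _cell(rng: random.Random, field: Field, keys: dict[str, list[str]]) -> str:
    if field.type == "xref":
        return rng.choice(keys[field.xref_entity.lower()])
    t = field.type if isinstance(field.type, str) else "string"
    if t in ("string", UNSET):
        return f"{rng.choice(_WORDS)}_{rng.randrange(1000)}"
    if t == "text":
        return " ".join(rng.choices(_WORDS, k=5))
    if t == "int":
        return str(rng.randrange(0, 10_000))
    if t == "decimal":
        return str(round(rng.uniform(0, 1000), 3))
    if t == "bool":
        return rng.choice(["true", "false"])
    if t == "date":
        return f"{rng.randint(2000, 2024):04d}-{rng.randint(1, 12):02d}-" \
               f"{rng.randint(1, 28):02d}"
    return rng.choice(_WORDS)


def random_data(model: Model, rows_per_entity: int,
                seed: int, defect: Optional[str] = None
                ) -> dict[str, TabularFile]:
    """Conforming tab-delimited files for every entity of a compiled model.

    Keys are unique, xref cells reference generated target keys, NULLs occur
    only in nillable fields; reproducible from *seed*.  ``defect=
    "bad_header"`` renames one header column so it matches no model field.
    """
    rng = random.Random(seed)
    order = entity_load_order(model)
    # keys first, so cross-references (including cycle edges) can point anywhere
    keys = {name.lower(): [f"{name}_{i + 1}" for i in range(rows_per_entity)]
            for name in order}
    files: dict[str, TabularFile] = {}
    for name in order:
        entity = model.entity(name)
        assert entity is not None
        key_field = entity.key_field()
        header = [f.name for f in entity.fields]
        rows = []
        for key in keys[name.lower()]:
            cells = []
            for f in entity.fields:
                if key_field is not None and f.name == key_field.name:
                    cells.append(key)
                elif f.nillable is True and rng.random() < 0.2:
                    cells.append("")
                elif f.unique is True:
                    cells.append(f"{name}_{f.name}_{len(rows) + 1}")
                else:
                    cells.append(_cell(rng, f, keys))
            rows.append(cells)
        files[entity.name] = TabularFile(entity=entity.name, header=header,
                                         rows=rows)
    if defect == "bad_header" and files:
        first = files[sorted(files)[0]]
        first.header[-1] = first.header[-1] + "s"
    return files
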