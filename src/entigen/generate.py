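"""Generation orchestrator: render every generator over a model into an
application directory.

The generated tree::

    out/
      schema.sql           relational DDL, referenced tables first
      application.cfg      application config (template-rendered)
      mappers/<Entity>.sql one data-mapper descriptor per entity (template)
      routes.json          REST route manifest
      ui.json              machine-readable UI layout descriptor
      docs/model.md        model documentation
      docs/model.dot       entity-relationship graph
      .entigen.json        manifest of generated files

Generation is a pure function of the model: no timestamps unless ``stamp``
is requested, byte-identical output on regeneration, and a regeneration
after a model change fully replaces the previously generated files (the
manifest records what to clear).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .docgen import er_graph, model_docs
from .dsl import apply_defaults, resolve_inheritance, validate
from .errors import ModelError
from .model import UNSET, Model, UIElement
from .rest import rest_routes
from .schema import schema_ddl
from .templates import builtin_templates, render

MANIFEST_NAME = ".entigen.json"


@dataclass(frozen=True)
class GeneratedFile:
    path: str           # relative to the output directory
    content: str
    template_id: str    # provenance: template id or generator name
    model_locus: str    # entity name or "model"


def ui_descriptor(model: Model) -> list[dict]:
    """The UI layout as plain data, with child-form links resolved."""

    def describe(element: UIElement, parent_form: UIElement | None) -> dict:
        out: dict = {"kind": element.kind, "name": element.name}
        if element.kind == "form":
            out["entity"] = element.entity
            out["view"] = element.view_mode if isinstance(element.view_mode, str) \
                else "record"
            link = _resolve_link(model, element, parent_form)
            if link is not None:
                out["link_field"] = link
        if element.kind == "plugin":
            out["plugin_id"] = element.plugin_id
        next_parent = element if element.kind == "form" else parent_form
        if element.kind != "plugin":
            out["children"] = [describe(c, next_parent)
                               for c in element.children]
        return out

    return [describe(el, None) for el in model.ui]


def _resolve_link(model: Model, form: UIElement,
                  parent_form: UIElement | None) -> str | None:
    """The xref field connecting a child form to its parent form's entity."""
    if parent_form is None:
        return None
    if form.link_field not in (UNSET, None):
        return form.link_field
    entity = model.entity(form.entity)  # type: ignore[arg-type]
    parent_entity = model.entity(parent_form.entity)  # type: ignore[arg-type]
    if entity is None or parent_entity is None:
        return None
    candidates = [f.name for f in entity.fields
                  if f.type == "xref" and isinstance(f.xref_entity, str)
                  and f.xref_entity.lower() == parent_entity.name.lower()]
    return candidates[0] if len(candidates) == 1 else None


def generate_files(model: Model, stamp: str | None = None) -> list[GeneratedFile]:
    """Render all generators over *model* (must be defaulted; inheritance is
    resolved here).  Raises ``GENERATE_INVALID_MODEL`` on validation errors."""
    model = apply_defaults(model)
    issues = [i for i in validate(model) if i.severity == "error"]
    if issues:
        raise ModelError(
            "GENERATE_INVALID_MODEL",
            "model has validation errors:\n" + "\n".join(str(i) for i in issues))
    resolved = resolve_inheritance(model)

    files: list[GeneratedFile] = [
        GeneratedFile("schema.sql", schema_ddl(resolved),
                      "schema_generator", "model"),
        GeneratedFile("routes.json",
                      json.dumps(rest_routes(resolved), indent=2,
                                 sort_keys=True) + "\n",
                      "rest_routes", "model"),
        GeneratedFile("ui.json",
                      json.dumps(ui_descriptor(resolved), indent=2) + "\n",
                      "ui_descriptor", "model"),
        GeneratedFile("docs/model.md", model_docs(resolved),
                      "doc_generator", "model"),
        GeneratedFile("docs/model.dot", er_graph(resolved),
                      "doc_generator", "model"),
    ]
    for template in builtin_templates():
        if template.scope == "model":
            files.append(GeneratedFile(template.output_path(resolved),
                                       render(template, resolved),
                                       template.id, "model"))
        else:
            for entity in resolved.entities:
                files.append(GeneratedFile(template.output_path(entity),
                                           render(template, entity),
                                           template.id, entity.name))
    if stamp is not None:
        files.append(GeneratedFile("generated-at.txt", stamp + "\n",
                                   "stamp", "model"))
    paths = [f.path for f in files]
    assert len(paths) == len(set(paths)), "generated paths must be unique"
    return sorted(files, key=lambda f: f.path)


def generate_application(model: Model, out: str | Path,
                         stamp: str | None = None) -> list[GeneratedFile]:
    """Write the generated application tree under *out*.

    Files recorded in a previous run's manifest are removed first, so the
    output is exactly the current model's generation — stale artifacts from
    an earlier model version never survive.
    """
    out = Path(out)
    files = generate_files(model, stamp=stamp)
    manifest_path = out / MANIFEST_NAME
    if manifest_path.exists():
        try:
            stale = json.loads(manifest_path.read_text(encoding="utf-8"))
        except json.JSONDecodeError:
            stale = []
        for rel in stale:
            target = out / rel
            if target.is_file():
                target.unlink()
    for generated in files:
        target = out / generated.path
        target.parent.mkdir(parents=True, exist_ok=True)
        target.write_text(generated.content, encoding="utf-8")
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    manifest_path.write_text(
        json.dumps([f.path for f in files], indent=2) + "\n",
        encoding="utf-8")
    return files
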