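"""Human-readable model documentation and the entity-relationship graph.

``model_docs`` writes one markdown section per entity (label, description,
field table, inheritance note); ``er_graph`` emits a DOT graph with one
record-shaped node per entity, a solid edge per cross-reference (labeled with
the field name) and a dashed edge per inheritance link.
"""

from __future__ import annotations

from .model import UNSET, Model


def _show(value, default: str = "") -> str:
    return value if isinstance(value, str) else default


def model_docs(model: Model) -> str:
    """Markdown documentation of the model, deterministic order (model order)."""
    lines = [f"# Model: {model.name}", ""]
    if not model.entities:
        return "\n".join(lines)
    lines += ["Entities: " + ", ".join(e.name for e in model.entities), ""]
    for entity in model.entities:
        label = _show(entity.label, entity.name)
        title = entity.name if label == entity.name else f"{entity.name} ({label})"
        lines.append(f"## {title}")
        lines.append("")
        if _show(entity.description):
            lines.append(entity.description)
            lines.append("")
        if entity.extends not in (UNSET, None):
            lines.append(f"*Extends `{entity.extends}`; inherited fields are "
                         f"listed below.*")
            lines.append("")
        lines.append("| field | type | nillable | readonly | unique | references |")
        lines.append("|---|---|---|---|---|---|")
        for f in entity.fields:
            type_text = f.type if isinstance(f.type, str) else "string"
            if type_text == "string" and isinstance(f.max_length, int):
                type_text = f"string({f.max_length})"
            ref = ""
            if f.type == "xref":
                ref = f"{f.xref_entity}.{f.xref_field}"
            lines.append(
                "| {name} | {type} | {nil} | {ro} | {uniq} | {ref} |".format(
                    name=f.name, type=type_text,
                    nil="yes" if f.nillable is True else "no",
                    ro="yes" if f.readonly is True else "no",
                    uniq="yes" if f.unique is True else "no",
                    ref=ref))
        lines.append("")
    return "\n".join(lines)


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"') \
        .replace("{", "\\{").replace("}", "\\}").replace("|", "\\|")


def er_graph(model: Model) -> str:
    """DOT source for the entity-relationship overview."""
    lines = [f'digraph "{_dot_escape(model.name)}" {{',
             "  node [shape=record];"]
    for entity in model.entities:
        fields = "\\l".join(_dot_escape(f.name) for f in entity.fields)
        label = f"{{{_dot_escape(entity.name)}|{fields}\\l}}" if entity.fields \
            else f"{{{_dot_escape(entity.name)}}}"
        lines.append(f'  "{_dot_escape(entity.name)}" [label="{label}"];')
    for entity in model.entities:
        for f in entity.fields:
            if f.type == "xref" and isinstance(f.xref_entity, str):
                lines.append(
                    f'  "{_dot_escape(entity.name)}" -> '
                    f'"{_dot_escape(f.xref_entity)}" '
                    f'[label="{_dot_escape(f.name)}"];')
        if entity.extends not in (UNSET, None):
            lines.append(
                f'  "{_dot_escape(entity.name)}" -> '
                f'"{_dot_escape(entity.extends)}" [style=dashed];')
    lines.append("}")
    return "\n".join(lines) + "\n"
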