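"""Template engine for the generator suite.

A generator template is plain text with command *holes* ``${...}``.  At
generation time every hole is filled from the model element the template is
applied to — the whole model for ``scope="model"`` templates, one entity at a
time for ``scope="per_entity"`` templates.

The command language is deliberately tiny and closed::

    ${Name(entity)}                  declared name, exactly as modeled
    ${name(entity)}                  declared name, lower-cased
    ${label(entity)}                 display label
    ${type(field)}                   DSL type of a field
    ${sql_type(field)}               DDL type of a field
    ${csv(entity.fields, name)}      apply a command to each element of a
                                     list, join with "," (or a custom
                                     separator given as third argument)

Arguments are dotted paths into the render context (``entity``,
``entity.fields``, ``model``, ``model.entities``) or, inside ``csv``, the
name of the command to map.  Rendering is pure: the same template and element
always produce the same text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .errors import TemplateError
from .model import Entity, Field, Model

_HOLE = re.compile(r"\$\{([^{}]*)\}")
_CALL = re.compile(r"^\s*(\w+)\s*\((.*)\)\s*$", re.S)


def _split_args(raw: str) -> list[str]:
    """Split a hole's argument list on top-level commas (quoted strings may
    contain commas)."""
    args: list[str] = []
    current = ""
    in_quote = False
    for ch in raw:
        if ch == '"':
            in_quote = not in_quote
            current += ch
        elif ch == "," and not in_quote:
            args.append(current.strip())
            current = ""
        else:
            current += ch
    if current.strip() or args:
        args.append(current.strip())
    return [a for a in args if a != ""]


# --- element commands -------------------------------------------------------

def _cmd_Name(el) -> str:
    return _declared_name(el)


def _cmd_name(el) -> str:
    return _declared_name(el).lower()


def _cmd_label(el) -> str:
    label = getattr(el, "label", None)
    return label if isinstance(label, str) else _declared_name(el)


def _cmd_type(el) -> str:
    if not isinstance(el, Field):
        raise TemplateError("TEMPLATE_BAD_ARGS", "type() applies to fields only")
    return el.type if isinstance(el.type, str) else "string"


def _cmd_sql_type(el) -> str:
    if not isinstance(el, Field):
        raise TemplateError("TEMPLATE_BAD_ARGS", "sql_type() applies to fields only")
    from .schema import sql_type_name  # local import avoids a cycle

    return sql_type_name(el)


def _declared_name(el) -> str:
    name = getattr(el, "name", None)
    if not isinstance(name, str):
        raise TemplateError("TEMPLATE_BAD_ARGS",
                            f"element {el!r} has no name")
    return name


#: The full command language; there are no others.
COMMANDS = {
    "Name": _cmd_Name,
    "name": _cmd_name,
    "label": _cmd_label,
    "type": _cmd_type,
    "sql_type": _cmd_sql_type,
}


@dataclass(frozen=True)
class Template:
    """One generator: a text body with command holes plus the relative output
    path its rendering is written to (``${Name}`` in the path is replaced by
    the element name for per-entity templates)."""

    id: str
    scope: str                  # "model" | "per_entity"
    body: str
    output_path_pattern: str

    def output_path(self, element) -> str:
        return self.output_path_pattern.replace("${Name}", _cmd_Name(element))


def _resolve_path(path: str, context: dict, position: int):
    parts = path.split(".")
    if parts[0] not in context:
        raise TemplateError(
            "TEMPLATE_BAD_ARGS",
            f"unknown reference {path!r}; context has {sorted(context)}",
            position)
    value = context[parts[0]]
    for attr in parts[1:]:
        if attr == "fields" and isinstance(value, Entity):
            value = value.fields
        elif attr == "entities" and isinstance(value, Model):
            value = value.entities
        else:
            raise TemplateError("TEMPLATE_BAD_ARGS",
                                f"cannot resolve {path!r}", position)
    return value


def _eval_hole(expr: str, context: dict, position: int) -> str:
    call = _CALL.match(expr)
    if not call:
        raise TemplateError("TEMPLATE_UNKNOWN_COMMAND",
                            f"hole ${{{expr}}} is not a command call", position)
    command, raw_args = call.group(1), _split_args(call.group(2))
    if command == "csv":
        if len(raw_args) not in (2, 3):
            raise TemplateError(
                "TEMPLATE_BAD_ARGS",
                f"csv takes (list, command[, separator]), got {len(raw_args)} "
                f"argument(s)", position)
        items = _resolve_path(raw_args[0], context, position)
        if not isinstance(items, list):
            raise TemplateError("TEMPLATE_BAD_ARGS",
                                f"{raw_args[0]!r} is not a list", position)
        inner = raw_args[1]
        if inner not in COMMANDS:
            raise TemplateError("TEMPLATE_UNKNOWN_COMMAND",
                                f"unknown command {inner!r} inside csv", position)
        sep = ","
        if len(raw_args) == 3:
            quoted = raw_args[2]
            if not (quoted.startswith('"') and quoted.endswith('"')):
                raise TemplateError("TEMPLATE_BAD_ARGS",
                                    "csv separator must be a quoted string",
                                    position)
            sep = quoted[1:-1]
        return sep.join(COMMANDS[inner](item) for item in items)
    if command not in COMMANDS:
        raise TemplateError("TEMPLATE_UNKNOWN_COMMAND",
                            f"unknown command {command!r}", position)
    if len(raw_args) != 1:
        raise TemplateError(
            "TEMPLATE_BAD_ARGS",
            f"{command} takes exactly one argument, got {len(raw_args)}",
            position)
    return COMMANDS[command](_resolve_path(raw_args[0], context, position))


def render(template: Template, element) -> str:
    """Fill every hole of *template* against *element* and return the text.

    *element* is a :class:`Model` for model-scope templates and an
    :class:`Entity` for per-entity templates; the render context exposes it
    as ``model`` / ``entity`` accordingly.
    """
    if template.scope == "model":
        if not isinstance(element, Model):
            raise TemplateError("TEMPLATE_BAD_ARGS",
                                f"template {template.id!r} has model scope")
        context = {"model": element}
    elif template.scope == "per_entity":
        if not isinstance(element, Entity):
            raise TemplateError("TEMPLATE_BAD_ARGS",
                                f"template {template.id!r} has per-entity scope")
        context = {"entity": element}
    else:
        raise TemplateError("TEMPLATE_BAD_ARGS",
                            f"unknown template scope {template.scope!r}")

    out: list[str] = []
    pos = 0
    for match in _HOLE.finditer(template.body):
        out.append(template.body[pos:match.start()])
        out.append(_eval_hole(match.group(1), context, match.start()))
        pos = match.end()
    out.append(template.body[pos:])
    rendered = "".join(out)
    if "${" in rendered:
        raise TemplateError("TEMPLATE_UNKNOWN_COMMAND",
                            "rendering left residual hole delimiters",
                            rendered.index("${"))
    return rendered


def builtin_templates() -> list[Template]:
    """Load the built-in generator templates shipped with the package.

    Each ``*.tmpl`` file starts with two header lines (``scope:`` and
    ``output:``) followed by the body.
    """
    directory = Path(__file__).parent / "templates"
    templates: list[Template] = []
    for path in sorted(directory.glob("*.tmpl")):
        text = path.read_text(encoding="utf-8")
        lines = text.split("\n")
        header = {}
        while lines and ":" in lines[0] and lines[0].split(":")[0] in ("scope", "output"):
            key, _, value = lines.pop(0).partition(":")
            header[key.strip()] = value.strip()
        templates.append(Template(
            id=path.stem,
            scope=header.get("scope", "model"),
            body="\n".join(lines),
            output_path_pattern=header.get("output", path.stem + ".txt"),
        ))
    return templates
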