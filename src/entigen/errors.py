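"""Error codes and exception types shared across the toolkit.

Every machine-detectable failure carries a stable code from the closed
enumeration below, so callers (CLI, REST layer, import reports) can react
without parsing message text.
"""

from __future__ import annotations

# Closed enumeration of issue / error codes.
CODES = frozenset(
    {
        # model structure
        "ENTITY_DUPLICATE",
        "EXTENDS_UNKNOWN",
        "MODEL_INHERITANCE_CYCLE",
        "FIELD_REDECLARED",
        "FIELD_ATTR_INVALID",
        "XREF_TARGET_MISSING",
        "XREF_TARGET_NOT_UNIQUE",
        "SCHEMA_XREF_CHAIN",
        "MODEL_XREF_CYCLE",
        # user-interface structure
        "UI_ENTITY_UNKNOWN",
        "UI_DUPLICATE_NAME",
        "UI_AMBIGUOUS_LINK",
        "UI_NO_LINK",
        "UI_LINK_UNKNOWN_FIELD",
        # parsing
        "PARSE_ERROR",
        "UNKNOWN_MARKUP",
        # templates / generation
        "TEMPLATE_UNKNOWN_COMMAND",
        "TEMPLATE_BAD_ARGS",
        "GENERATE_INVALID_MODEL",
        # data exchange
        "IMPORT_UNKNOWN_COLUMN",
        "IMPORT_UNKNOWN_ENTITY",
        "XREF_UNRESOLVED",
        "NOT_NILLABLE",
        "TYPE_INVALID",
        "DUPLICATE_KEY",
        # runtime data layer
        "READONLY_VIOLATION",
        "REFERENTIAL_BLOCK",
        "NOT_FOUND",
        "QUERY_UNKNOWN_FIELD",
        "QUERY_BAD_OPERATOR",
        "ENTITY_UNKNOWN",
        # reverse engineering
        "EXTRACT_IO_ERROR",
        "EXTRACT_UNMAPPED_TYPE",
        "EXTRACT_COMPOSITE_FK",
        "EXTRACT_FK_NOT_UNIQUE",
    }
)


class EntigenError(Exception):
    """Base error: a stable ``code`` plus a human-readable message."""

    def __init__(self, code: str, message: str):
        assert code in CODES, f"unknown error code {code!r}"
        self.code = code
        super().__init__(message)

    @property
    def message(self) -> str:
        return self.args[0]


class ModelError(EntigenError):
    """Raised by model operations whose preconditions are violated."""


class ParseError(EntigenError):
    """Malformed or unknown DSL markup; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None, code: str = "PARSE_ERROR"):
        super().__init__(code, message)
        self.line = line


class TemplateError(EntigenError):
    """Bad hole in a generator template; carries the hole's offset in the body."""

    def __init__(self, code: str, message: str, position: int | None = None):
        super().__init__(code, message)
        self.position = position


class StoreError(EntigenError):
    """Constraint violation or lookup failure in the runtime data layer."""


class ExtractError(EntigenError):
    """Unreadable input to schema introspection."""
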