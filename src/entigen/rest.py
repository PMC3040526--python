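"""REST/JSON programmatic interface generated from the model.

Per entity (entity names lower-cased in paths, JSON field names verbatim):

    GET    /api/v1/{entity}           query params = equals filters;
                                      _offset, _limit, _sort control paging
    GET    /api/v1/{entity}/{key}
    POST   /api/v1/{entity}           body = JSON record
    PUT    /api/v1/{entity}/{key}     body = JSON changes
    DELETE /api/v1/{entity}/{key}

Collection responses use the envelope
``{"items": [...], "total": n, "offset": o, "limit": l}``; errors map to 4xx
with ``{"code": ..., "message": ...}``.  Each UI plugin declared in the model
becomes a named extension point mounted at ``/plugin/{plugin_id}`` where an
operator can register a handler at runtime.

The application is a plain WSGI callable, so it can be exercised in-process
or served with any WSGI server (:func:`serve` uses the stdlib one).
"""

from __future__ import annotations

import json
import logging
import re
from typing import Callable
from urllib.parse import parse_qsl

from .errors import StoreError
from .model import Model
from .store import Filter, Page, Store, parse_value

log = logging.getLogger(__name__)

_STATUS = {
    200: "200 OK", 201: "201 Created", 400: "400 Bad Request",
    404: "404 Not Found", 405: "405 Method Not Allowed",
    409: "409 Conflict", 500: "500 Internal Server Error",
}
_ERROR_STATUS = {
    "NOT_FOUND": 404,
    "ENTITY_UNKNOWN": 404,
    "QUERY_UNKNOWN_FIELD": 400,
    "QUERY_BAD_OPERATOR": 400,
    "TYPE_INVALID": 400,
    "NOT_NILLABLE": 400,
    "XREF_UNRESOLVED": 400,
    "DUPLICATE_KEY": 409,
    "READONLY_VIOLATION": 409,
    "REFERENTIAL_BLOCK": 409,
}


def rest_routes(model: Model) -> dict:
    """The route manifest: one entry per entity plus plugin mount points."""
    entities = {}
    for entity in model.entities:
        path = f"/api/v1/{entity.name.lower()}"
        key = entity.key_field()
        entities[entity.name.lower()] = {
            "entity": entity.name,
            "collection": path,
            "item": path + "/{key}",
            "key": key.name if key else None,
            "methods": ["GET", "POST", "PUT", "DELETE"],
        }
    plugins = {}
    for _, el in model.walk_ui():
        if el.kind == "plugin":
            plugins[el.plugin_id] = f"/plugin/{el.plugin_id}"
    return {"entities": entities, "plugins": plugins}


class RestApp:
    """WSGI application over one :class:`~entigen.store.Store`."""

    _route = re.compile(r"^/api/v1/([^/]+)(?:/([^/]+))?$")
    _plugin_route = re.compile(r"^/plugin/([^/]+)(/.*)?$")

    def __init__(self, store: Store):
        self.store = store
        self.model = store.model
        self._entities = {e.name.lower(): e for e in self.model.entities}
        self._plugin_ids = {el.plugin_id for _, el in self.model.walk_ui()
                            if el.kind == "plugin"}
        self._plugins: dict[str, Callable] = {}

    # -- extension points ----------------------------------------------------

    def register_plugin(self, plugin_id: str, handler: Callable) -> None:
        """Attach a handler to a plugin extension point declared in the model.

        ``handler(method, subpath, body) -> (status, payload)``.
        """
        if plugin_id not in self._plugin_ids:
            raise StoreError("ENTITY_UNKNOWN",
                             f"model declares no plugin {plugin_id!r}")
        self._plugins[plugin_id] = handler

    # -- WSGI ---------------------------------------------------------------

    def __call__(self, environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/")
        try:
            status, payload = self._dispatch(method, path, environ)
        except StoreError as exc:
            status = _ERROR_STATUS.get(exc.code, 400)
            payload = {"code": exc.code, "message": exc.message}
        except (ValueError, json.JSONDecodeError) as exc:
            status, payload = 400, {"code": "PARSE_ERROR", "message": str(exc)}
        body = json.dumps(payload).encode("utf-8")
        log.info("%s %s -> %d", method, path, status)
        start_response(_STATUS[status], [
            ("Content-Type", "application/json; charset=utf-8"),
            ("Content-Length", str(len(body))),
        ])
        return [body]

    def _dispatch(self, method: str, path: str, environ):
        plugin = self._plugin_route.match(path)
        if plugin:
            plugin_id, subpath = plugin.group(1), plugin.group(2) or "/"
            handler = self._plugins.get(plugin_id)
            if handler is None:
                raise StoreError("ENTITY_UNKNOWN",
                                 f"no handler registered for plugin "
                                 f"{plugin_id!r}")
            return handler(method, subpath, self._read_body(environ))

        match = self._route.match(path)
        if not match:
            raise StoreError("NOT_FOUND", f"no route {path!r}")
        entity_low, key_raw = match.group(1), match.group(2)
        entity = self._entities.get(entity_low)
        if entity is None:
            raise StoreError("ENTITY_UNKNOWN", f"unknown entity {entity_low!r}")
        key_field = entity.key_field()
        key = parse_value(key_field, key_raw) if key_raw is not None else None

        if method == "GET" and key is None:
            return self._collection(entity, environ)
        if method == "GET":
            return 200, self.store.get(entity.name, key)
        if method == "POST" and key is None:
            record = self._read_body(environ)
            return 201, self.store.add(entity.name, record)
        if method == "PUT" and key is not None:
            changes = self._read_body(environ)
            return 200, self.store.update(entity.name, key, changes)
        if method == "DELETE" and key is not None:
            removed = self.store.remove(entity.name, key)
            return 200, {"removed": removed}
        raise StoreError("NOT_FOUND",
                         f"unsupported {method} on {path!r}")

    def _collection(self, entity, environ):
        params = parse_qsl(environ.get("QUERY_STRING", ""))
        filters: list[Filter] = []
        offset, limit, sort = 0, Page().limit, None
        for name, raw in params:
            if name == "_offset":
                offset = int(raw)
            elif name == "_limit":
                limit = int(raw)
            elif name == "_sort":
                sort = raw
            else:
                field = entity.field(name)
                if field is None:
                    raise StoreError(
                        "QUERY_UNKNOWN_FIELD",
                        f"entity {entity.name!r} has no field {name!r}")
                filters.append(Filter(field.name, "equals",
                                      parse_value(field, raw)))
        page = Page(offset=offset, limit=limit)
        records, total = self.store.find(entity.name, filters, page, sort)
        return 200, {"items": records, "total": total,
                     "offset": page.offset, "limit": page.limit}

    @staticmethod
    def _read_body(environ):
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        if length == 0:
            return None
        raw = environ["wsgi.input"].read(length)
        return json.loads(raw.decode("utf-8"))


def serve(model: Model, store: Store, port: int = 8080):  # pragma: no cover
    """Run the generated service with the stdlib WSGI server (blocking)."""
    from wsgiref.simple_server import make_server

    app = RestApp(store)
    with make_server("127.0.0.1", port, app) as httpd:
        log.info("serving %s on http://127.0.0.1:%d/api/v1/", model.name, port)
        httpd.serve_forever()
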