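import io
import json

import pytest

import entigen as eg
from entigen.rest import RestApp
from entigen.store import Store


@pytest.fixture
def example_xml() -> str:
    return eg.EXAMPLE_MODEL_XML


@pytest.fixture
def example_model():
    """The worked-example model, compiled (defaults, validation, inheritance)."""
    return eg.compile_model(eg.EXAMPLE_MODEL_XML)


@pytest.fixture
def example_store(example_model):
    store = Store(example_model)
    store.add("Experiment", {"ID": "E1", "Name": "yeast heat", "Medium": "glucose",
                             "Stress": "heat", "Temperature": 30.0})
    store.add("Experiment", {"ID": "E2", "Name": "yeast cold", "Medium": "galactose",
                             "Stress": "cold", "Temperature": 12.5})
    store.add("Sample", {"ID": "S1", "Experiment": "E1", "Tissue": "culture"})
    store.add("Sample", {"ID": "S2", "Experiment": "E1"})
    store.add("Sample", {"ID": "S3", "Experiment": "E2"})
    store.add("Hybridization", {"ID": "H1", "Experiment": "E1", "Sample": "S1",
                                "Dye": "cy3"})
    yield store
    store.close()


def wsgi_call(app: RestApp, method: str, path: str, body=None, query: str = ""):
    """Drive the WSGI app in-process; returns (status code, decoded JSON)."""
    raw = json.dumps(body).encode() if body is not None else b""
    environ = {
        "REQUEST_METHOD": method,
        "PATH_INFO": path,
        "QUERY_STRING": query,
        "CONTENT_LENGTH": str(len(raw)),
        "wsgi.input": io.BytesIO(raw),
    }
    captured = {}

    def start_response(status, headers):
        captured["status"] = int(status.split()[0])

    chunks = app(environ, start_response)
    return captured["status"], json.loads(b"".join(chunks))
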