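"""DDL generation: type mapping and behavioral constraint fidelity on the
embedded engine."""

import sqlite3

import pytest

from entigen.dsl import apply_defaults, compile_model, parse_model
from entigen.errors import ModelError
from entigen.fixtures import FixtureSpec, random_model
from entigen.model import Field
from entigen.schema import create_table_ddl, schema_ddl, sql_type
from entigen.dsl import serialize_model


def execute(ddl: str) -> sqlite3.Connection:
    conn = sqlite3.connect(":memory:")
    conn.execute("PRAGMA foreign_keys = ON")
    conn.executescript(ddl)
    return conn


@pytest.mark.parametrize("field,expected", [
    (Field(name="x", type="string", max_length=255), "VARCHAR(255)"),
    (Field(name="x", type="string", max_length=64), "VARCHAR(64)"),
    (Field(name="x", type="text"), "TEXT"),
    (Field(name="x", type="int"), "INTEGER"),
    (Field(name="x", type="decimal"), "DOUBLE PRECISION"),
    (Field(name="x", type="bool"), "BOOLEAN"),
    (Field(name="x", type="date"), "DATE"),
])
def test_type_mapping(field, expected):
    assert sql_type(field) == expected


def test_xref_column_takes_referenced_type():
    xml = ('<molgenis name="m">'
           '<entity name="A"><field name="id" type="int" unique="true"/></entity>'
           '<entity name="B"><field name="id" unique="true"/>'
           '<field name="a" type="xref" xref_entity="A" xref_field="id"/>'
           '</entity></molgenis>')
    model = compile_model(xml)
    a_ref = model.entity("B").field("a")
    assert sql_type(a_ref, model) == "INTEGER"


def test_xref_chain_raises():
    # bypass validation deliberately: the chain must still fail loudly
    xml = ('<molgenis name="m">'
           '<entity name="A"><field name="id" unique="true"/></entity>'
           '<entity name="B"><field name="a" type="xref" xref_entity="A"'
           ' xref_field="id" unique="true"/></entity>'
           '<entity name="C"><field name="b" type="xref" xref_entity="B"'
           ' xref_field="a"/></entity></molgenis>')
    model = apply_defaults(parse_model(xml))
    with pytest.raises(ModelError) as err:
        sql_type(model.entity("C").field("b"), model)
    assert err.value.code == "SCHEMA_XREF_CHAIN"


class TestConstraintFidelity:
    """Model constraints are verified behaviorally by violating inserts."""

    def test_not_null_and_unique_enforced(self, example_model):
        conn = execute(schema_ddl(example_model))
        conn.execute("INSERT INTO Experiment (ID, Name, Medium, Stress) "
                     "VALUES ('E1', 'n', 'glucose', 'heat')")
        with pytest.raises(sqlite3.IntegrityError):
            conn.execute("INSERT INTO Experiment (ID, Name, Medium, Stress) "
                         "VALUES (NULL, 'n', 'm', 's')")
        with pytest.raises(sqlite3.IntegrityError):
            conn.execute("INSERT INTO Experiment (ID, Name, Medium, Stress) "
                         "VALUES ('E1', 'dup', 'm', 's')")

    def test_foreign_key_enforced(self, example_model):
        ddl = schema_ddl(example_model)
        assert 'FOREIGN KEY ("Experiment") REFERENCES "Experiment" ("ID")' \
            not in create_table_ddl(example_model.entity("Experiment"))
        conn = execute(ddl)
        with pytest.raises(sqlite3.IntegrityError):
            conn.execute("INSERT INTO Sample (ID, Experiment) "
                         "VALUES ('S1', 'E9')")

    def test_entity_extending_one_field_parent_has_one_column(self):
        xml = ('<molgenis name="m">'
               '<entity name="A"><field name="id" unique="true"/></entity>'
               '<entity name="B" extends="A"/></molgenis>')
        model = compile_model(xml)
        ddl = create_table_ddl(model.entity("B"), model)
        assert ddl.count('"id"') == 1
        assert ddl.count(",") == 0  # a single column, no other clauses


class TestScript:
    def test_referenced_tables_created_first(self, example_model):
        script = schema_ddl(example_model)
        assert script.index('CREATE TABLE "Experiment"') \
            < script.index('CREATE TABLE "Sample"')

    def test_empty_model_empty_script(self):
        model = compile_model('<molgenis name="empty"/>')
        assert schema_ddl(model) == ""

    @pytest.mark.parametrize("seed", range(1, 51))
    def test_random_valid_models_execute_cleanly(self, seed):
        model = random_model(FixtureSpec(seed=seed, n_entities=5))
        compiled = compile_model(serialize_model(model))
        conn = execute(schema_ddl(compiled))
        tables = {r[0] for r in conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")}
        assert tables == {e.name for e in compiled.entities}


class TestValidationSoundness:
    """Any model whose generated schema misbehaves must already have been
    flagged by validate()."""

    @pytest.mark.parametrize("defect", ["xref_missing", "cycle", "dup_field"])
    @pytest.mark.parametrize("seed", range(1, 11))
    def test_defective_models_are_flagged_before_generation(self, defect, seed):
        from entigen.dsl import resolve_inheritance, validate

        model = apply_defaults(random_model(
            FixtureSpec(seed=seed, n_entities=4, defect=defect)))
        issues = [i for i in validate(model) if i.severity == "error"]
        schema_broken = False
        try:
            execute(schema_ddl(resolve_inheritance(model)))
        except (ModelError, sqlite3.Error):
            schema_broken = True
        if schema_broken:
            assert issues, f"schema failed but validate() was silent ({defect})"
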