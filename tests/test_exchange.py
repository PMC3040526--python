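"""Tab-delimited exchange: header validation, row-atomic import, round trip,
deferred cycle resolution."""

import pytest

from entigen.dsl import compile_model, serialize_model
from entigen.errors import StoreError
from entigen.exchange import (
    TabularFile,
    export_entity,
    import_batch,
    import_file,
)
from entigen.fixtures import FixtureSpec, random_data, random_model
from entigen.store import Store


def tsv(entity, header, rows):
    return TabularFile(entity=entity, header=header, rows=rows)


class TestImport:
    def test_resolvable_xref_row_is_added(self, example_model, example_store):
        report = import_file(example_store, example_model.entity("Sample"),
                             tsv("Sample", ["ID", "Experiment"],
                                 [["S9", "E1"]]))
        assert (report.rows_added, report.errors) == (1, [])

    def test_unresolvable_xref_row_is_reported(self, example_model):
        store = Store(example_model)
        report = import_file(store, example_model.entity("Sample"),
                             tsv("Sample", ["ID", "Experiment"],
                                 [["S1", "E1"]]))
        assert report.rows_added == 0
        assert [e.code for e in report.errors] == ["XREF_UNRESOLVED"]

    def test_unknown_header_column_rejects_whole_file(self, example_model,
                                                      example_store):
        with pytest.raises(StoreError) as err:
            import_file(example_store, example_model.entity("Experiment"),
                        tsv("Experiment", ["ID", "Mediums"], [["E9", "x"]]))
        assert err.value.code == "IMPORT_UNKNOWN_COLUMN"

    def test_duplicate_key_within_file_is_a_row_error(self, example_model,
                                                      example_store):
        report = import_file(example_store, example_model.entity("Sample"),
                             tsv("Sample", ["ID", "Experiment"],
                                 [["S8", "E1"], ["S8", "E1"]]))
        assert report.rows_added == 1
        assert [e.code for e in report.errors] == ["DUPLICATE_KEY"]

    def test_update_mode_requires_existing_key(self, example_model,
                                               example_store):
        report = import_file(example_store, example_model.entity("Experiment"),
                             tsv("Experiment", ["ID", "Medium"],
                                 [["E1", "raffinose"], ["E9", "x"]]),
                             mode="update")
        assert (report.rows_updated, report.rows_added) == (1, 0)
        assert [e.code for e in report.errors] == ["NOT_FOUND"]
        assert example_store.get("Experiment", "E1")["Medium"] == "raffinose"

    def test_add_update_upserts_on_key(self, example_model, example_store):
        before = example_store.count("Experiment")
        report = import_file(
            example_store, example_model.entity("Experiment"),
            tsv("Experiment", ["ID", "Name", "Medium", "Stress"],
                [["E1", "renamed", "glucose", "heat"],
                 ["E9", "fresh", "maltose", "none"]]))
        assert (report.rows_added, report.rows_updated) == (1, 1)
        assert example_store.count("Experiment") == before + 1

    def test_conservation_invariant(self, example_model, example_store):
        file = tsv("Sample", ["ID", "Experiment"],
                   [["S7", "E1"], ["S7", "E1"], ["X1", "NOPE"]])
        report = import_file(example_store, example_model.entity("Sample"), file)
        assert report.rows_added + report.rows_updated \
            + len(report.rejected_rows) == len(file.rows)


class TestExport:
    def test_header_and_rows(self, example_model, example_store):
        file = export_entity(example_store, example_model.entity("Experiment"))
        assert file.header == ["ID", "Name", "Medium", "Stress",
                               "Temperature", "StartDate"]
        assert len(file.rows) == 2

    def test_xref_cell_holds_referenced_key(self, example_model, example_store):
        file = export_entity(example_store, example_model.entity("Sample"))
        experiment_cell = file.header.index("Experiment")
        assert file.rows[0][experiment_cell] == "E1"

    def test_empty_table_exports_header_only(self, example_model):
        store = Store(example_model)
        file = export_entity(store, example_model.entity("Experiment"))
        assert file.rows == [] and file.header[0] == "ID"

    def test_null_encodes_as_empty_cell_and_survives_quoting(self, example_model,
                                                             example_store):
        example_store.add("Sample", {"ID": "S9", "Experiment": "E1",
                                     "Tissue": 'has\ttab and "quote"'})
        file = export_entity(example_store, example_model.entity("Sample"))
        text = file.to_text()
        reread = TabularFile.from_text("Sample", text)
        assert reread.rows == file.rows
        s2 = [r for r in reread.rows if r[0] == "S2"][0]
        assert s2[file.header.index("Tissue")] == ""


class TestBatch:
    def test_files_processed_in_load_order(self, example_model):
        store = Store(example_model)
        files = {
            "Sample": tsv("Sample", ["ID", "Experiment"], [["S1", "E1"]]),
            "Experiment": tsv("Experiment",
                              ["ID", "Name", "Medium", "Stress"],
                              [["E1", "n", "m", "s"]]),
        }
        reports = import_batch(store, example_model, files)
        assert [r.entity for r in reports] == ["Experiment", "Sample"]
        assert all(not r.errors for r in reports)

    def test_unknown_entity_rejected(self, example_model):
        store = Store(example_model)
        with pytest.raises(StoreError) as err:
            import_batch(store, example_model,
                         {"Nope": tsv("Nope", ["ID"], [])})
        assert err.value.code == "IMPORT_UNKNOWN_ENTITY"

    def test_bad_row_does_not_poison_other_files(self, example_model):
        store = Store(example_model)
        files = {
            "Experiment": tsv("Experiment", ["ID", "Name", "Medium", "Stress"],
                              [["E1", "n", "m", "s"]]),
            "Sample": tsv("Sample", ["ID", "Experiment"],
                          [["S1", "E1"], ["S2", "E9"]]),
        }
        reports = {r.entity: r for r in import_batch(store, example_model, files)}
        assert reports["Experiment"].rows_added == 1
        assert reports["Sample"].rows_added == 1
        assert [e.code for e in reports["Sample"].errors] == ["XREF_UNRESOLVED"]

    def test_nillable_cycle_resolved_in_second_pass(self):
        xml = ('<molgenis name="m">'
               '<entity name="A"><field name="id" unique="true"/>'
               '<field name="b" type="xref" xref_entity="B" xref_field="id"'
               ' nillable="true"/></entity>'
               '<entity name="B"><field name="id" unique="true"/>'
               '<field name="a" type="xref" xref_entity="A" xref_field="id"/>'
               '</entity></molgenis>')
        model = compile_model(xml)
        store = Store(model)
        files = {
            "A": tsv("A", ["id", "b"], [["a1", "b1"]]),
            "B": tsv("B", ["id", "a"], [["b1", "a1"]]),
        }
        reports = import_batch(store, model, files)
        assert all(not r.errors for r in reports)
        assert store.get("A", "a1")["b"] == "b1"
        assert store.get("B", "b1")["a"] == "a1"


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [2, 11, 23])
    def test_import_then_export_reproduces_random_data(self, seed):
        model = compile_model(serialize_model(
            random_model(FixtureSpec(seed=seed, n_entities=4))))
        store = Store(model)
        data = random_data(model, 6, seed)
        reports = import_batch(store, model, data)
        assert all(not r.errors and r.rows_added == 6 for r in reports)
        for entity in model.entities:
            exported = export_entity(store, entity)
            assert exported.header == data[entity.name].header
            assert sorted(map(tuple, exported.rows)) \
                == sorted(map(tuple, data[entity.name].rows))

    def test_zero_rows_gives_header_only_files(self, example_model):
        data = random_data(example_model, 0, seed=1)
        assert all(f.rows == [] for f in data.values())
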