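"""Modeling language: parsing, defaults, inheritance, validation, ordering,
serialization."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import entigen as eg
from entigen.dsl import (
    apply_defaults,
    compile_model,
    entity_load_order,
    models_equal,
    parse_model,
    resolve_inheritance,
    serialize_model,
    validate,
)
from entigen.errors import ModelError, ParseError
from entigen.fixtures import FixtureSpec, random_model
from entigen.model import UNSET


def wrap(inner: str, name: str = "m") -> str:
    return f'<molgenis name="{name}">{inner}</molgenis>'


class TestParse:
    def test_worked_example_structure(self, example_xml):
        model = parse_model(example_xml)
        assert [e.name for e in model.entities] == [
            "Experiment", "Sample", "Hybridization"]
        experiment = model.entity("Experiment")
        assert len(experiment.fields) == 6
        names = [f.name for f in experiment.fields]
        assert {"ID", "Medium", "Stress"} <= set(names)

    def test_unset_attributes_stay_unset(self, example_xml):
        model = parse_model(example_xml)
        medium = model.entity("Experiment").field("Medium")
        assert medium.type is UNSET
        assert medium.nillable is UNSET
        assert medium.max_length is UNSET

    def test_empty_document_is_a_valid_model(self):
        model = parse_model(wrap(""))
        assert model.entities == [] and model.ui == []
        assert validate(apply_defaults(model)) == []

    def test_xref_typo_parses_but_fails_validation(self):
        xml = wrap(
            '<entity name="Experiment"><field name="ID" unique="true"/></entity>'
            '<entity name="Sample"><field name="ID" unique="true"/>'
            '<field name="Experiment" type="xref" xref_entity="Experimnt"'
            ' xref_field="ID"/></entity>')
        model = apply_defaults(parse_model(xml))
        codes = [i.code for i in validate(model)]
        assert "XREF_TARGET_MISSING" in codes

    def test_malformed_xml_reports_line(self):
        with pytest.raises(ParseError) as err:
            parse_model("<molgenis>\n<entity\n</molgenis>")
        assert err.value.line is not None

    def test_unknown_attribute_strict_vs_lax(self):
        xml = wrap('<entity name="A" colour="red"><field name="ID"/></entity>')
        with pytest.raises(ParseError) as err:
            parse_model(xml, strict=True)
        assert "colour" in str(err.value)
        model = parse_model(xml, strict=False)
        assert [w.code for w in model.parse_warnings] == ["UNKNOWN_MARKUP"]


class TestDefaults:
    def test_name_only_field_becomes_string_255(self):
        model = apply_defaults(parse_model(wrap(
            '<entity name="Experiment"><field name="Medium"/></entity>')))
        medium = model.entity("Experiment").field("Medium")
        assert medium.type == "string"
        assert medium.max_length == 255
        assert medium.nillable is False
        assert medium.readonly is False
        assert medium.unique is False
        assert medium.label == "Medium"

    def test_explicit_attributes_survive(self):
        model = apply_defaults(parse_model(wrap(
            '<entity name="A"><field name="x" type="decimal" nillable="true"'
            ' label="The X"/></entity>')))
        x = model.entity("A").field("x")
        assert (x.type, x.nillable, x.label) == ("decimal", True, "The X")
        assert x.max_length is UNSET  # only strings get a length

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_idempotent_on_random_models(self, seed):
        model = random_model(FixtureSpec(seed=seed, n_entities=4))
        once = apply_defaults(model)
        assert apply_defaults(once) == once


class TestInheritance:
    def test_parent_fields_come_first(self):
        xml = wrap('<entity name="A"><field name="id" unique="true"/></entity>'
                   '<entity name="B" extends="A"><field name="x"/></entity>')
        model = resolve_inheritance(apply_defaults(parse_model(xml)))
        assert [f.name for f in model.entity("B").fields] == ["id", "x"]
        assert model.entity("B").extends == "A"

    def test_three_level_chain_matches_brute_force(self):
        xml = wrap('<entity name="A"><field name="a" unique="true"/></entity>'
                   '<entity name="B" extends="A"><field name="b"/></entity>'
                   '<entity name="C" extends="B"><field name="c"/></entity>')
        model = apply_defaults(parse_model(xml))

        # oracle: repeated parent lookup, prepending own fields each step
        def flatten(name):
            entity = model.entity(name)
            own = [f.name for f in entity.own_fields]
            if entity.extends is UNSET:
                return own
            return flatten(entity.extends) + own

        resolved = resolve_inheritance(model)
        for name in ("A", "B", "C"):
            assert [f.name for f in resolved.entity(name).fields] == flatten(name)
        assert len(resolved.entity("C").fields) == 3

    def test_cycle_is_an_error(self):
        xml = wrap('<entity name="A" extends="B"><field name="x"/></entity>'
                   '<entity name="B" extends="A"><field name="y"/></entity>')
        with pytest.raises(ModelError) as err:
            resolve_inheritance(apply_defaults(parse_model(xml)))
        assert err.value.code == "MODEL_INHERITANCE_CYCLE"

    def test_redeclared_parent_field_rejected(self):
        xml = wrap('<entity name="A"><field name="id"/></entity>'
                   '<entity name="B" extends="A"><field name="ID"/></entity>')
        with pytest.raises(ModelError) as err:
            resolve_inheritance(apply_defaults(parse_model(xml)))
        assert err.value.code == "FIELD_REDECLARED"


class TestValidate:
    def test_worked_example_is_clean(self, example_xml):
        assert validate(apply_defaults(parse_model(example_xml))) == []

    def test_xref_to_non_unique_field(self):
        xml = wrap('<entity name="A"><field name="id"/></entity>'
                   '<entity name="B"><field name="id" unique="true"/>'
                   '<field name="a" type="xref" xref_entity="A" xref_field="id"/>'
                   '</entity>')
        codes = [i.code for i in validate(apply_defaults(parse_model(xml)))]
        assert "XREF_TARGET_NOT_UNIQUE" in codes

    def test_two_xrefs_to_parent_need_explicit_link(self):
        xml = wrap(
            '<entity name="P"><field name="id" unique="true"/></entity>'
            '<entity name="C"><field name="id" unique="true"/>'
            '<field name="p1" type="xref" xref_entity="P" xref_field="id"/>'
            '<field name="p2" type="xref" xref_entity="P" xref_field="id"/>'
            '</entity>'
            '<ui><form name="parent" entity="P">'
            '<form name="children" entity="C"/></form></ui>')
        codes = [i.code for i in validate(apply_defaults(parse_model(xml)))]
        assert "UI_AMBIGUOUS_LINK" in codes
        # an explicit link resolves the ambiguity
        fixed = xml.replace('<form name="children" entity="C"/>',
                            '<form name="children" entity="C" link="p1"/>')
        assert validate(apply_defaults(parse_model(fixed))) == []

    def test_duplicate_entity_names_case_insensitive(self):
        xml = wrap('<entity name="A"><field name="id" unique="true"/></entity>'
                   '<entity name="a"><field name="id" unique="true"/></entity>')
        codes = [i.code for i in validate(apply_defaults(parse_model(xml)))]
        assert "ENTITY_DUPLICATE" in codes

    def test_xref_chain_is_rejected(self):
        xml = wrap(
            '<entity name="A"><field name="id" unique="true"/></entity>'
            '<entity name="B"><field name="id" unique="true"/>'
            '<field name="a" type="xref" xref_entity="A" xref_field="id"'
            ' unique="true"/></entity>'
            '<entity name="C"><field name="id" unique="true"/>'
            '<field name="b" type="xref" xref_entity="B" xref_field="a"/>'
            '</entity>')
        codes = [i.code for i in validate(apply_defaults(parse_model(xml)))]
        assert "SCHEMA_XREF_CHAIN" in codes

    def test_non_nillable_self_reference_rejected(self):
        xml = wrap('<entity name="A"><field name="id" unique="true"/>'
                   '<field name="parent" type="xref" xref_entity="A"'
                   ' xref_field="id"/></entity>')
        codes = [i.code for i in validate(apply_defaults(parse_model(xml)))]
        assert "MODEL_XREF_CYCLE" in codes
        nillable = xml.replace('xref_field="id"/>', 'xref_field="id" nillable="true"/>')
        assert validate(apply_defaults(parse_model(nillable))) == []


def load_order_oracle(model):
    """All permutations satisfying every non-self xref precedence, for models
    small enough to enumerate."""
    model = resolve_inheritance(apply_defaults(model))
    names = [e.name for e in model.entities]
    index = {n: i for i, n in enumerate(names)}
    constraints = set()
    for entity in model.entities:
        for f in entity.fields:
            if f.type == "xref" and model.entity(f.xref_entity) is not None:
                target = model.entity(f.xref_entity).name
                if target.lower() != entity.name.lower():
                    constraints.add((target, entity.name))
    valid = []
    for perm in itertools.permutations(names):
        pos = {n: i for i, n in enumerate(perm)}
        if all(pos[a] < pos[b] for a, b in constraints):
            valid.append(perm)
    return valid, index


class TestLoadOrder:
    def test_referenced_entity_precedes_referrer(self, example_model):
        order = entity_load_order(example_model)
        assert order.index("Experiment") < order.index("Sample")
        assert order.index("Sample") < order.index("Hybridization")

    def test_chain_orders_target_first(self):
        xml = wrap(
            '<entity name="C"><field name="id" unique="true"/>'
            '<field name="b" type="xref" xref_entity="B" xref_field="id"/></entity>'
            '<entity name="B"><field name="id" unique="true"/>'
            '<field name="a" type="xref" xref_entity="A" xref_field="id"/></entity>'
            '<entity name="A"><field name="id" unique="true"/></entity>')
        model = apply_defaults(parse_model(xml))
        order = entity_load_order(model)
        assert order == ["A", "B", "C"]
        valid, index = load_order_oracle(model)
        assert tuple(order) in valid
        assert tuple(order) == min(valid, key=lambda p: [index[n] for n in p])

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_matches_brute_force_permutation_oracle(self, seed):
        model = random_model(FixtureSpec(seed=seed,
                                         n_entities=2 + seed % 6,
                                         xref_density=0.8))
        order = entity_load_order(apply_defaults(model))
        valid, index = load_order_oracle(model)
        assert tuple(order) in valid
        assert tuple(order) == min(valid, key=lambda p: [index[n] for n in p])

    def test_hard_cycle_is_an_error(self):
        xml = wrap(
            '<entity name="A"><field name="id" unique="true"/>'
            '<field name="b" type="xref" xref_entity="B" xref_field="id"/></entity>'
            '<entity name="B"><field name="id" unique="true"/>'
            '<field name="a" type="xref" xref_entity="A" xref_field="id"/></entity>')
        with pytest.raises(ModelError) as err:
            entity_load_order(apply_defaults(parse_model(xml)))
        assert err.value.code == "MODEL_XREF_CYCLE"

    def test_nillable_edge_relaxes_the_cycle(self):
        xml = wrap(
            '<entity name="A"><field name="id" unique="true"/>'
            '<field name="b" type="xref" xref_entity="B" xref_field="id"'
            ' nillable="true"/></entity>'
            '<entity name="B"><field name="id" unique="true"/>'
            '<field name="a" type="xref" xref_entity="A" xref_field="id"/></entity>')
        model = apply_defaults(parse_model(xml))
        assert validate(model) == []
        assert entity_load_order(model) == ["A", "B"]


class TestSerialize:
    def test_worked_example_round_trip(self, example_xml):
        model = parse_model(example_xml)
        assert models_equal(model, parse_model(serialize_model(model)))

    def test_all_default_field_serializes_to_bare_name(self):
        xml = wrap('<entity name="A"><field name="Medium"/></entity>')
        text = serialize_model(apply_defaults(parse_model(xml)))
        assert '<field name="Medium" />' in text

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_random_model_round_trip(self, seed):
        model = random_model(FixtureSpec(seed=seed, n_entities=5))
        assert models_equal(model, parse_model(serialize_model(model)))

    def test_serialized_resolved_model_does_not_duplicate_inherited_fields(self):
        xml = wrap('<entity name="A"><field name="id" unique="true"/></entity>'
                   '<entity name="B" extends="A"><field name="x"/></entity>')
        compiled = compile_model(xml)
        text = serialize_model(compiled)
        reparsed = parse_model(text)
        assert [f.name for f in reparsed.entity("B").own_fields] == ["x"]
        assert models_equal(compiled, reparsed)
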