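"""Shared fixtures: the packaged schema fixture, a small hand-built
manifest covering every data type, and the four-segment workflow set."""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from modco.fixture import fixture_manifest
from modco.records import DescriptorAssignment, UnitRecord
from modco.schema import Concept, ConceptCollection, ConceptValue, SchemaManifest
from modco.synthetic import generate_gbol2_workflow
from modco.vocab import (
    DataTypeToken,
    ElementaryDomain,
    OperationDomain,
    OTHER_VALUE_LABEL,
)

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

NS = "http://www.mod-co.net/wiki/modco:"


@pytest.fixture(scope="session")
def fixture_schema():
    return fixture_manifest()


@pytest.fixture(scope="session")
def gbol2_records(fixture_schema):
    return generate_gbol2_workflow(0, fixture_schema)


def make_value(i: int, label: str, other: bool = False) -> ConceptValue:
    return ConceptValue(value_id=f"v{i}", label=label, is_other_value=other)


def small_manifest() -> SchemaManifest:
    """Five concepts, one per data type, plus two collections."""
    m = SchemaManifest(version="1.0", namespace_base=NS)
    m.collections["traits"] = ConceptCollection("traits", "Object traits")
    m.collections["traits-tissue"] = ConceptCollection(
        "traits-tissue", "Tissue", parent="traits")
    concepts = [
        Concept("c1", "unit physical (host) organism muscle tissue <category>",
                DataTypeToken.CATEGORICAL, 4,
                values=(make_value(1, "cardiac"), make_value(2, "skeletal"),
                        make_value(3, "smooth muscle"),
                        make_value(4, OTHER_VALUE_LABEL, other=True)),
                collections=("traits", "traits-tissue")),
        Concept("c2", "unit digital measurement device URI <string>",
                DataTypeToken.TEXT, 3),
        Concept("c3", "unit physical measurement sample mass <value>",
                DataTypeToken.QUANTITATIVE, 3),
        Concept("c4", "unit digital measurement marker gene read <string>",
                DataTypeToken.SEQUENCE, 4),
        Concept("c5", "unit physical substrate category <category> <string>",
                DataTypeToken.CATEGORICAL_PLUS_TEXT, 2,
                values=(make_value(1, "soil"), make_value(2, "bark"),
                        make_value(3, OTHER_VALUE_LABEL, other=True))),
    ]
    for c in concepts:
        c.uri = NS + c.name.replace(" ", "_")
        from modco.schema import page_slug
        c.uri = NS + page_slug(c.name)
        m.concepts[c.concept_id] = c
    return m


@pytest.fixture()
def small_schema():
    return small_manifest()


def random_record(manifest: SchemaManifest, rng: random.Random, unit_id: str,
                  corrupt: bool = False) -> UnitRecord:
    """One record with one assignment per concept; ``corrupt=True`` plants a
    single out-of-vocabulary categorical value."""
    assignments = []
    categorical = [c for c in manifest.concepts.values() if c.is_categorical]
    bad_concept = rng.choice(categorical).concept_id if corrupt and categorical else None
    for c in manifest.concepts.values():
        if c.is_categorical:
            if c.concept_id == bad_concept:
                assignments.append(DescriptorAssignment(c.concept_id, "not a state"))
            else:
                regular = [v for v in c.values if not v.is_other_value]
                assignments.append(
                    DescriptorAssignment(c.concept_id, rng.choice(regular).label))
        elif c.data_type is DataTypeToken.QUANTITATIVE:
            assignments.append(DescriptorAssignment(
                c.concept_id, f"{rng.uniform(0, 100):.2f}", unit_of_measure="mg"))
        elif c.data_type is DataTypeToken.SEQUENCE:
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 60)))
            assignments.append(DescriptorAssignment(c.concept_id, seq))
        else:
            assignments.append(DescriptorAssignment(c.concept_id, f"note {unit_id}"))
    return UnitRecord(
        unit_id=unit_id,
        elementary_domain=rng.choice(list(ElementaryDomain)),
        operation_domain=rng.choice(list(OperationDomain)),
        assignments=tuple(assignments),
    )
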