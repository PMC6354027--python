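"""The packaged schema fixture: MOD-CO version 1.0 by the numbers.

The full 653-concept inventory of the published schema lives on the
mod-co.net wiki and is not redistributed here.  This module instead builds
a *statistics-complete, content-exemplary* stand-in, synthetic by
construction: every aggregate of the published version 1.0 release is
reproduced exactly —

* 653 concepts: 398 text, 238 categorical, 7 quantitative, 10 sequence;
* 1810 predefined concept values (2463 concept+value pages in total);
* five hierarchy levels with 61 / 277 / 49 / 215 / 51 concepts;
* 13 concept collections, 8 of them subdivided into 24 subcollections,
  with the published per-(sub)collection membership counts, e.g.
  Unit property domains [Digital: 235 — Physical: 380] and
  Unit operation domains [Transformation: 241 — Measurement: 174 —
  Transaction: 112] (memberships overlap; 615 and 527 both differ from
  653 because collection assignment is not a partition);

while the concept *content* is exemplary: the handful of concepts whose
names and value lists are part of the published schema documentation
(``unit digital measurement device URI <string>``, the muscle-tissue
descriptor with states [cardiac, skeletal, smooth muscle, other value],
the level-0 identifier and record-management descriptors, ...) appear
verbatim; the remaining concepts are grammar-conformant numbered
placeholders.  Construction is deterministic, so the fixture is identical
across runs and machines.
"""

from __future__ import annotations

from functools import lru_cache

from .schema import Concept, ConceptValue, SchemaManifest
from .synthetic import (
    CollectionPlan,
    DEFAULT_NAMESPACE,
    ManifestSpec,
    generate_manifest,
)
from .vocab import DataTypeToken, ElementaryDomain, OperationDomain, OTHER_VALUE_LABEL

__all__ = [
    "SCHEMA_VERSION",
    "N_CONCEPTS",
    "N_VALUES",
    "N_BY_DATA_TYPE",
    "N_BY_LEVEL",
    "COLLECTION_SIZES",
    "fixture_manifest",
    "fixture_spec",
]

SCHEMA_VERSION = "1.0"
#: Seed of the deterministic fixture build (the 1.0 release date, 2018-03-28).
FIXTURE_SEED = 20180328

N_CONCEPTS = 653
N_VALUES = 1810

N_BY_DATA_TYPE: dict[DataTypeToken, int] = {
    DataTypeToken.TEXT: 398,
    DataTypeToken.CATEGORICAL: 238,
    DataTypeToken.QUANTITATIVE: 7,
    DataTypeToken.SEQUENCE: 10,
}

N_BY_LEVEL: dict[int, int] = {0: 61, 1: 277, 2: 49, 3: 215, 4: 51}

#: Published membership counts per (sub)collection.
COLLECTION_SIZES: dict[str, int] = {
    "identifiers-doi": 2,
    "identifiers-id": 82,
    "identifiers-name": 158,
    "identifiers-uri": 66,
    "space-time": 99,
    "unit-property-domains-digital": 235,
    "unit-property-domains-physical": 380,
    "unit-operation-domains-transformation": 241,
    "unit-operation-domains-measurement": 174,
    "unit-operation-domains-transaction": 112,
    "operational-details-method": 49,
    "operational-details-parameter": 20,
    "operational-details-protocol": 23,
    "operational-specifications": 60,
    "operational-tools-hardware": 63,
    "operational-tools-software": 54,
    "operational-tools-enzyme-reagent": 16,
    "environmental-object-types-host-organism": 26,
    "environmental-object-types-substrate": 15,
    "environmental-object-traits": 27,
    "agent-related-aspects": 81,
    "legal-issues-agreement-compliance-permit": 21,
    "legal-issues-project": 5,
    "data-record-management": 22,
}


def _cat(cid: str, name: str, level: int, labels: tuple[str, ...],
         with_other: bool = False) -> Concept:
    values = tuple(
        ConceptValue(value_id=f"v{i + 1}", label=lab) for i, lab in enumerate(labels))
    if with_other:
        values += (ConceptValue(value_id=f"v{len(labels) + 1}",
                                label=OTHER_VALUE_LABEL, is_other_value=True),)
    return Concept(concept_id=cid, name=name,
                   data_type=DataTypeToken.CATEGORICAL, hierarchy_level=level,
                   values=values)


def _text(cid: str, name: str, level: int) -> Concept:
    return Concept(concept_id=cid, name=name, data_type=DataTypeToken.TEXT,
                   hierarchy_level=level)


#: Concepts that appear verbatim in the published schema documentation.
_EXEMPLARS: tuple[Concept, ...] = (
    _text("e01", "unit identifier <string>", 0),
    _text("e02", "unit identifier preceding <string>", 0),
    _text("e03", "unit identifier origin <string>", 0),
    _text("e04", "unit identifier subsequent <string>", 0),
    _text("e05", "unit record creation date/time <string>", 0),
    _text("e06", "unit record creation agent <string>", 0),
    _cat("e07", "unit domain elementary <category>", 0,
         ("physical", "digital")),
    _cat("e08", "unit operation domain <category>", 0,
         ("transformation", "measurement", "transaction")),
    _text("e09", "unit digital measurement device URI <string>", 3),
    _text("e10", "unit physical transformation community genomic analysis "
          "sequencing library index primer name <string>", 3),
    _cat("e11", "unit physical (host) organism muscle tissue <category>", 4,
         ("cardiac", "skeletal", "smooth muscle"), with_other=True),
    _cat("e12", "unit physical transformation protocol modification <category>", 3,
         ("property identifier", "property parameters", "property specification",
          "modification identifier", "modification parameters",
          "modification specification"), with_other=True),
)

# Exemplar tallies subtracted from the published totals to size the
# placeholder decks: 8 text + 4 categorical concepts; levels 0 x8 / 3 x3 /
# 4 x1; 16 predefined values; name-segment tallies per the grammar.
_PLACEHOLDER_DTYPES = {
    DataTypeToken.TEXT: 398 - 8,
    DataTypeToken.CATEGORICAL: 238 - 4,
    DataTypeToken.QUANTITATIVE: 7,
    DataTypeToken.SEQUENCE: 10,
}
_PLACEHOLDER_LEVELS = {0: 61 - 8, 1: 277, 2: 49, 3: 215 - 3, 4: 51 - 1}
_PLACEHOLDER_ELEMENTARY = {
    ElementaryDomain.PHYSICAL: 380 - 3,   # e10, e11, e12
    ElementaryDomain.DIGITAL: 235 - 1,    # e09
    None: 653 - 380 - 235 - 8,            # bare 'unit' concepts; e01..e08
}
_PLACEHOLDER_OPERATIONS = {
    OperationDomain.TRANSFORMATION: 241 - 2,  # e10, e12
    OperationDomain.MEASUREMENT: 174 - 1,     # e09
    OperationDomain.TRANSACTION: 112,
    None: 653 - 241 - 174 - 112 - 9,
}
_PLACEHOLDER_PROPERTIES = {
    "DOI": 2,
    "ID": 82 - 4,     # e01..e04 sit in the ID subcollection by fiat
    "name": 158 - 1,  # e10
    "URI": 66 - 1,    # e09
    None: 0,          # filled below to reach the total
}
_PLACEHOLDER_PROPERTIES[None] = (
    sum(_PLACEHOLDER_DTYPES.values())
    - sum(v for k, v in _PLACEHOLDER_PROPERTIES.items() if k is not None))


def _collection_plans() -> tuple[CollectionPlan, ...]:
    plans: list[CollectionPlan] = [
        CollectionPlan("schema-hierarchy", "Schema hierarchy"),
        CollectionPlan("identifiers", "Identifiers"),
        CollectionPlan("space-time", "Space-time details and specifications",
                       n_members=COLLECTION_SIZES["space-time"]),
        CollectionPlan("unit-property-domains", "Unit property domains"),
        CollectionPlan("unit-operation-domains", "Unit operation domains"),
        CollectionPlan("operational-details", "Operational details"),
        CollectionPlan("operational-specifications", "Operational specifications",
                       n_members=COLLECTION_SIZES["operational-specifications"]),
        CollectionPlan("operational-tools", "Operational tools"),
        CollectionPlan("environmental-object-types", "Environmental object types"),
        CollectionPlan("environmental-object-traits", "Environmental object traits",
                       n_members=COLLECTION_SIZES["environmental-object-traits"]),
        CollectionPlan("agent-related-aspects", "Agent-related aspects",
                       n_members=COLLECTION_SIZES["agent-related-aspects"]),
        CollectionPlan("legal-issues", "Legal issues-related aspects"),
        CollectionPlan("data-record-management", "Data record management aspects",
                       n_members=COLLECTION_SIZES["data-record-management"],
                       preset=("e05", "e06")),
    ]
    level_names = ("general", "operation general", "object general",
                   "operation specific", "object specific")
    for lvl, label in enumerate(level_names):
        plans.append(CollectionPlan(
            f"schema-hierarchy-level-{lvl}", f"level {lvl} ({label})",
            parent="schema-hierarchy", role="hierarchy-level", level=lvl,
            selector="level"))
    plans += [
        CollectionPlan("identifiers-doi", "DOI", parent="identifiers",
                       selector="property:DOI",
                       n_members=COLLECTION_SIZES["identifiers-doi"]),
        CollectionPlan("identifiers-id", "ID", parent="identifiers",
                       selector="property:ID", preset=("e01", "e02", "e03", "e04"),
                       n_members=COLLECTION_SIZES["identifiers-id"]),
        CollectionPlan("identifiers-name", "Name", parent="identifiers",
                       selector="property:name", preset=("e10",),
                       n_members=COLLECTION_SIZES["identifiers-name"]),
        CollectionPlan("identifiers-uri", "URI", parent="identifiers",
                       selector="property:URI", preset=("e09",),
                       n_members=COLLECTION_SIZES["identifiers-uri"]),
        CollectionPlan("unit-property-domains-digital", "Digital",
                       parent="unit-property-domains", selector="elementary:digital",
                       n_members=COLLECTION_SIZES["unit-property-domains-digital"]),
        CollectionPlan("unit-property-domains-physical", "Physical",
                       parent="unit-property-domains", selector="elementary:physical",
                       n_members=COLLECTION_SIZES["unit-property-domains-physical"]),
        CollectionPlan("unit-operation-domains-transformation", "Transformation",
                       parent="unit-operation-domains",
                       selector="operation:transformation",
                       n_members=COLLECTION_SIZES["unit-operation-domains-transformation"]),
        CollectionPlan("unit-operation-domains-measurement", "Measurement",
                       parent="unit-operation-domains",
                       selector="operation:measurement",
                       n_members=COLLECTION_SIZES["unit-operation-domains-measurement"]),
        CollectionPlan("unit-operation-domains-transaction", "Transaction",
                       parent="unit-operation-domains",
                       selector="operation:transaction",
                       n_members=COLLECTION_SIZES["unit-operation-domains-transaction"]),
        CollectionPlan("operational-details-method", "Method",
                       parent="operational-details",
                       n_members=COLLECTION_SIZES["operational-details-method"]),
        CollectionPlan("operational-details-parameter", "Parameter",
                       parent="operational-details",
                       n_members=COLLECTION_SIZES["operational-details-parameter"]),
        CollectionPlan("operational-details-protocol", "Protocol",
                       parent="operational-details", preset=("e12",),
                       n_members=COLLECTION_SIZES["operational-details-protocol"]),
        CollectionPlan("operational-tools-hardware", "Hardware",
                       parent="operational-tools",
                       n_members=COLLECTION_SIZES["operational-tools-hardware"]),
        CollectionPlan("operational-tools-software", "Software",
                       parent="operational-tools",
                       n_members=COLLECTION_SIZES["operational-tools-software"]),
        CollectionPlan("operational-tools-enzyme-reagent", "Enzyme, reagent",
                       parent="operational-tools",
                       n_members=COLLECTION_SIZES["operational-tools-enzyme-reagent"]),
        CollectionPlan("environmental-object-types-host-organism", "(Host) organism",
                       parent="environmental-object-types", preset=("e11",),
                       n_members=COLLECTION_SIZES["environmental-object-types-host-organism"]),
        CollectionPlan("environmental-object-types-substrate",
                       "(Environmental) substrate",
                       parent="environmental-object-types",
                       n_members=COLLECTION_SIZES["environmental-object-types-substrate"]),
        CollectionPlan("legal-issues-agreement-compliance-permit",
                       "Agreement, compliance, permit", parent="legal-issues",
                       n_members=COLLECTION_SIZES["legal-issues-agreement-compliance-permit"]),
        CollectionPlan("legal-issues-project", "Project", parent="legal-issues",
                       n_members=COLLECTION_SIZES["legal-issues-project"]),
    ]
    return tuple(plans)


def fixture_spec() -> ManifestSpec:
    """The generation spec realizing the version 1.0 aggregate statistics."""
    return ManifestSpec(
        n_by_data_type=_PLACEHOLDER_DTYPES,
        n_by_level=_PLACEHOLDER_LEVELS,
        version=SCHEMA_VERSION,
        namespace_base=DEFAULT_NAMESPACE,
        n_values_total=N_VALUES,
        elementary_counts=_PLACEHOLDER_ELEMENTARY,
        operation_counts=_PLACEHOLDER_OPERATIONS,
        property_counts=_PLACEHOLDER_PROPERTIES,
        collections=_collection_plans(),
        exemplars=_EXEMPLARS,
    )


@lru_cache(maxsize=1)
def fixture_manifest() -> SchemaManifest:
    """Build (once per process) the deterministic packaged fixture."""
    return generate_manifest(fixture_spec(), FIXTURE_SEED)
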