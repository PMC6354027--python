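"""SKOS-typed schema mapping: substitution, fallbacks, coverage."""

from __future__ import annotations

import pytest

from modco.errors import MappingError
from modco.mapping import (
    FallbackPolicy,
    MappingTable,
    coverage_report,
    identity_table,
    map_record,
    read_mapping_table,
    write_mapping_table,
)
from modco.records import DescriptorAssignment, UnitRecord
from modco.schema import Concept, SchemaManifest
from modco.vocab import DataTypeToken, ElementaryDomain, MatchType, OperationDomain

from conftest import NS, make_value, small_manifest


def target_manifest() -> SchemaManifest:
    """A 'foreign' schema with a differently-worded muscle vocabulary."""
    m = SchemaManifest(version="t1", namespace_base=NS)
    m.concepts["t1"] = Concept(
        "t1", "unit physical tissue type <category>", DataTypeToken.CATEGORICAL, 2,
        values=(make_value(1, "heart muscle"), make_value(2, "skeletal muscle"),
                make_value(3, "other value", other=True)),
        uri=NS + "t1")
    m.concepts["t2"] = Concept(
        "t2", "unit digital measurement device note <string>",
        DataTypeToken.TEXT, 3, uri=NS + "t2")
    return m


def crosswalk() -> MappingTable:
    table = MappingTable()
    table.add_concept("c1", "t1", MatchType.CLOSE)
    table.add_concept("c2", "t2", MatchType.EXACT)
    table.add_value("c1", "cardiac", "heart muscle")
    table.add_value("c1", "skeletal", "skeletal muscle")
    return table


def record(*assignments):
    return UnitRecord("u1", ElementaryDomain.PHYSICAL, OperationDomain.MEASUREMENT,
                      assignments=tuple(assignments))


def test_exact_value_substitution():
    mapped, report = map_record(
        record(DescriptorAssignment("c1", "cardiac")), crosswalk(), target_manifest())
    assert mapped.assignments == (DescriptorAssignment("t1", "heart muscle"),)
    assert (report.n_mapped, report.n_fallback, report.n_dropped) == (1, 0, 0)


def test_unmapped_value_falls_back_to_other_value():
    """'smooth muscle' has no correspondence: it lands on the target's
    'other value' state with the original wording as supplement."""
    mapped, report = map_record(
        record(DescriptorAssignment("c1", "smooth muscle")),
        crosswalk(), target_manifest(), policy=FallbackPolicy.OTHER_VALUE)
    (a,) = mapped.assignments
    assert a.value == "other value"
    assert a.supplement == "smooth muscle"
    assert report.fallback_wordings == [("c1", "smooth muscle")]


def test_whole_text_policy_carries_wording():
    mapped, _ = map_record(
        record(DescriptorAssignment("c1", "smooth muscle")),
        crosswalk(), target_manifest(), policy=FallbackPolicy.WHOLE_TEXT)
    assert mapped.assignments[0].value == "smooth muscle"


def test_drop_policy_omits_assignment():
    mapped, report = map_record(
        record(DescriptorAssignment("c1", "smooth muscle")),
        crosswalk(), target_manifest(), policy=FallbackPolicy.DROP)
    assert mapped.assignments == ()
    assert report.n_dropped == 1


def test_unmapped_concept_counts_as_dropped():
    mapped, report = map_record(
        record(DescriptorAssignment("c3", "1.5")), crosswalk(), target_manifest())
    assert mapped.assignments == ()
    assert report.drop_reasons == [("c3", "no-concept-map")]


def test_inexact_match_needs_opt_in():
    """A broadMatch correspondence carries metadata but does not
    substitute values unless explicitly allowed."""
    table = crosswalk()
    table.add_concept("c1", "t1", MatchType.BROAD)
    src = record(DescriptorAssignment("c1", "cardiac"))
    mapped, report = map_record(src, table, target_manifest())
    assert mapped.assignments[0].value == "other value"  # fell back
    mapped2, _ = map_record(src, table, target_manifest(), allow_inexact=True)
    assert mapped2.assignments[0].value == "heart muscle"


@pytest.mark.parametrize("policy", list(FallbackPolicy))
def test_fallback_conservation(policy):
    """mapped + fallback + dropped equals the number of assignments for
    every policy."""
    src = record(
        DescriptorAssignment("c1", "cardiac"),
        DescriptorAssignment("c1", "smooth muscle"),
        DescriptorAssignment("c2", "free text"),
        DescriptorAssignment("c3", "9.1"),
    )
    _, report = map_record(src, crosswalk(), target_manifest(), policy=policy)
    assert report.total == len(src.assignments)


def test_identity_mapping_is_lossless(fixture_schema, gbol2_records):
    table = identity_table(fixture_schema)
    for r in gbol2_records:
        mapped, report = map_record(r, table, fixture_schema)
        assert mapped == r
        assert report.n_fallback == report.n_dropped == 0


def test_mapping_never_invents_target_values():
    table = crosswalk()
    table.value_maps[("c1", "smooth muscle")] = "striated"  # not in target
    with pytest.raises(MappingError, match="striated"):
        map_record(record(DescriptorAssignment("c1", "smooth muscle")),
                   table, target_manifest())


def test_concept_map_outside_target_is_error():
    table = MappingTable()
    table.add_concept("c1", "missing", MatchType.EXACT)
    with pytest.raises(MappingError, match="missing"):
        map_record(record(DescriptorAssignment("c1", "cardiac")),
                   table, target_manifest())


def test_value_map_without_concept_map_is_error():
    table = MappingTable()
    table.add_value("c1", "cardiac", "heart muscle")
    with pytest.raises(MappingError):
        table.check()


def test_coverage_empty_table():
    stats = coverage_report(MappingTable(), small_manifest(), target_manifest())
    assert stats.concept_coverage == 0.0
    assert all(mapped == 0 for mapped, _ in stats.per_collection.values())


def test_coverage_value_fraction():
    table = MappingTable()
    table.add_concept("c1", "t1", MatchType.EXACT)
    for label in ("cardiac", "skeletal", "smooth muscle"):
        table.add_value("c1", label, label)
    stats = coverage_report(table, small_manifest(), target_manifest())
    assert stats.value_coverage["c1"] == pytest.approx(0.75)  # 3 of 4 states


def test_identity_coverage_is_complete(fixture_schema):
    table = identity_table(fixture_schema)
    stats = coverage_report(table, fixture_schema, fixture_schema)
    assert stats.concept_coverage == 1.0
    assert all(v == 1.0 for v in stats.value_coverage.values())
    assert all(mapped == total for mapped, total in stats.per_collection.values())


def test_table_csv_roundtrip(tmp_path):
    table = crosswalk()
    path = tmp_path / "map.csv"
    text = write_mapping_table(table, path)
    back = read_mapping_table(path)
    assert write_mapping_table(back) == text
    assert back.concept_maps["c1"].match_type is MatchType.CLOSE
    assert back.value_maps[("c1", "cardiac")] == "heart muscle"
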