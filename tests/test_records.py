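"""Unit-record validation and the CSV record-table round-trip."""

from __future__ import annotations

import pytest

from modco.errors import RecordFormatError, RecordReferenceError
from modco.records import (
    DescriptorAssignment,
    Severity,
    UnitRecord,
    UnknownColumnWarning,
    read_records,
    validate_assignment,
    validate_record,
    write_records,
)
from modco.schema import SchemaManifest
from modco.vocab import ElementaryDomain, OperationDomain

from conftest import small_manifest


@pytest.fixture()
def manifest():
    return small_manifest()


@pytest.mark.parametrize("assignment,severity,reason", [
    (DescriptorAssignment("c1", "cardiac"), Severity.PASS, "ok"),
    (DescriptorAssignment("c1", "Skeletal"), Severity.PASS, "ok"),  # case-insensitive
    (DescriptorAssignment("c1", "striated"), Severity.FAIL, "value-not-in-vocabulary"),
    (DescriptorAssignment("c1", "other value", supplement="striated"),
     Severity.PASS, "ok"),
    (DescriptorAssignment("c1", "other value"),
     Severity.WARN, "other-value-without-supplement"),
    (DescriptorAssignment("c3", "12.5", unit_of_measure="mg"), Severity.PASS, "ok"),
    (DescriptorAssignment("c3", "abc"), Severity.FAIL, "non-numeric"),
    (DescriptorAssignment("c4", "acgtACGTnry"), Severity.PASS, "ok"),
    (DescriptorAssignment("c4", "ACGT!123"), Severity.FAIL,
     "invalid-sequence-characters"),
    (DescriptorAssignment("c2", "free text"), Severity.PASS, "ok"),
    (DescriptorAssignment("c5", "soil", supplement="sandy"), Severity.PASS, "ok"),
    (DescriptorAssignment("c1", ""), Severity.FAIL, "empty-value"),
])
def test_assignment_validation(manifest, assignment, severity, reason):
    issue = validate_assignment(assignment, manifest)
    assert issue.severity is severity
    assert issue.reason == reason


def test_unknown_concept_is_reference_error_not_fail(manifest):
    with pytest.raises(RecordReferenceError):
        validate_assignment(DescriptorAssignment("nope", "x"), manifest)


def test_self_loop_is_record_failure(manifest):
    r = UnitRecord("u1", ElementaryDomain.PHYSICAL, OperationDomain.TRANSFORMATION,
                   preceding_ids=frozenset({"u1"}))
    report = validate_record(r, manifest)
    assert [i.reason for i in report.failures] == ["self-loop"]


def test_failure_count_matches_bad_assignments(manifest):
    r = UnitRecord(
        "u1", ElementaryDomain.PHYSICAL, OperationDomain.MEASUREMENT,
        assignments=(
            DescriptorAssignment("c1", "striated"),
            DescriptorAssignment("c3", "not-a-number"),
            DescriptorAssignment("c2", "fine"),
        ))
    report = validate_record(r, manifest)
    assert len(report.failures) == 2
    assert report.ok is False


def test_validation_independent_of_manifest_order(manifest):
    r = UnitRecord(
        "u1", ElementaryDomain.PHYSICAL, OperationDomain.MEASUREMENT,
        assignments=(DescriptorAssignment("c1", "striated"),
                     DescriptorAssignment("c4", "ACGT")))
    permuted = SchemaManifest(version=manifest.version,
                              namespace_base=manifest.namespace_base,
                              collections=manifest.collections)
    for cid in reversed(list(manifest.concepts)):
        permuted.concepts[cid] = manifest.concepts[cid]
    assert ([i.reason for i in validate_record(r, manifest).issues]
            == [i.reason for i in validate_record(r, permuted).issues])


def test_gbol2_records_validate_cleanly(fixture_schema, gbol2_records):
    for r in gbol2_records:
        report = validate_record(r, fixture_schema)
        assert report.ok and not report.warnings, report.issues


# --- CSV round-trip -------------------------------------------------------


def chain_records(manifest):
    ids = ["A", "B", "C", "D"]
    out = []
    for i, uid in enumerate(ids):
        out.append(UnitRecord(
            unit_id=uid,
            elementary_domain=ElementaryDomain.PHYSICAL,
            operation_domain=OperationDomain.TRANSFORMATION,
            preceding_ids=frozenset(ids[i - 1:i]),
            origin_id="A" if i else None,
            assignments=(
                DescriptorAssignment("c1", "other value", supplement=f"w{i}"),
                DescriptorAssignment("c3", f"{i}.5", unit_of_measure="mg"),
                DescriptorAssignment("c2", f"note {uid}"),
            ),
        ))
    return out


def test_csv_roundtrip_identity(manifest, tmp_path):
    records = chain_records(manifest)
    path = tmp_path / "records.csv"
    text1 = write_records(records, manifest, path)
    back = read_records(path, manifest)
    assert write_records(back, manifest) == text1
    assert [r.unit_id for r in back] == ["A", "B", "C", "D"]
    assert back[3].preceding_ids == frozenset({"C"})
    # read-back assignments follow manifest column order: c1, c2, c3
    assert back[1].assignments[0].supplement == "w1"
    assert back[1].assignments[2].unit_of_measure == "mg"


def test_multivalued_categorical_columns(manifest):
    r = UnitRecord(
        "u1", ElementaryDomain.PHYSICAL, OperationDomain.MEASUREMENT,
        assignments=(DescriptorAssignment("c1", "cardiac"),
                     DescriptorAssignment("c1", "skeletal")))
    text = write_records([r], manifest)
    assert "#2" in text.splitlines()[0]
    back = read_records(text, manifest)
    assert [a.value for a in back[0].assignments] == ["cardiac", "skeletal"]


def test_header_only_table_is_empty(manifest):
    assert read_records("unit_id,unit_domain_elementary,unit_operation_domain\n",
                        manifest) == []


def test_duplicate_unit_id_rejected(manifest):
    text = ("unit_id,unit_domain_elementary,unit_operation_domain\n"
            "u1,physical,measurement\nu1,physical,measurement\n")
    with pytest.raises(RecordFormatError, match="u1"):
        read_records(text, manifest)


def test_missing_unit_id_column_rejected(manifest):
    with pytest.raises(RecordFormatError, match="unit_id"):
        read_records("name,unit_domain_elementary\n", manifest)


def test_unknown_column_warns_not_errors(manifest):
    text = ("unit_id,unit_domain_elementary,unit_operation_domain,mystery\n"
            "u1,physical,measurement,42\n")
    with pytest.warns(UnknownColumnWarning, match="mystery"):
        records = read_records(text, manifest)
    assert len(records) == 1
    assert records[0].assignments == ()
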