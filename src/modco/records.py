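"""Unit data records: descriptor assignments, validation, CSV round-trip.

A *unit record* describes one physical or digital unit (a field sample, a
DNA extract, an amplicon pool, a read data set ...) through descriptor
assignments drawn from a schema manifest, plus the identifier links that
concatenate records into a workflow:

* ``unit_id`` — the record's own identifier;
* ``preceding_ids`` — parent units it was derived from (an extract's
  preceding unit is the sample; a pool's preceding units are the pooled
  amplicons);
* ``origin_id`` — the declared root unit (typically the field sample);
* ``subsequent_ids`` — child units (e.g. the pool an amplicon went into).

Validation has three severities: PASS, WARN (usable but flagged, e.g. an
``other value`` assignment lacking its free-text supplement) and FAIL
(type mismatch, value outside the controlled vocabulary, malformed
record).  Failures are report entries, never exceptions.

Record tables are CSV (UTF-8): one row per unit, reserved identifier and
domain columns, and one column per concept headed by the concept's full
name (repeat a column with ``' #N'`` suffixed for multi-valued
assignments).  Cell encodings are documented on :func:`format_cell`.
"""

from __future__ import annotations

import csv
import enum
import io
import os
import warnings
from dataclasses import dataclass, field

from .errors import RecordFormatError, RecordReferenceError
from .schema import Concept, SchemaManifest
from .vocab import (
    DataTypeToken,
    ElementaryDomain,
    OperationDomain,
    OTHER_VALUE_LABEL,
    SEQUENCE_ALPHABET,
)

__all__ = [
    "DescriptorAssignment",
    "RecordMeta",
    "UnitRecord",
    "Severity",
    "ValidationIssue",
    "ValidationReport",
    "validate_assignment",
    "validate_record",
    "read_records",
    "write_records",
    "RESERVED_COLUMNS",
    "UnknownColumnWarning",
]

#: Reserved CSV headers, in canonical column order.
RESERVED_COLUMNS = (
    "unit_id",
    "unit_id_preceding",
    "unit_id_origin",
    "unit_id_subsequent",
    "unit_domain_elementary",
    "unit_operation_domain",
    "unit_record_created",
    "unit_record_agent",
)

_LIST_SEP = ";"
_SUPPLEMENT_SEP = " | "


class UnknownColumnWarning(UserWarning):
    """A record table column does not match any manifest concept."""


@dataclass(frozen=True)
class DescriptorAssignment:
    """One concept/value pair of a unit record.

    ``value`` holds the payload as a string: free text, a sequence, a
    categorical value label, or the numeric literal of a quantitative
    payload.  ``supplement`` carries the free-text addition of categorical
    assignments (mandatory in spirit for ``other value``); ``unit_of_measure``
    the unit string of quantitative payloads.
    """

    concept_id: str
    value: str
    supplement: str | None = None
    unit_of_measure: str | None = None


@dataclass(frozen=True)
class RecordMeta:
    """Record-management metadata (data entry, not unit provenance)."""

    created: str | None = None
    agent: str | None = None


@dataclass
class UnitRecord:
    """One data record for a physical or digital unit."""

    unit_id: str
    elementary_domain: ElementaryDomain
    operation_domain: OperationDomain
    preceding_ids: frozenset[str] = frozenset()
    origin_id: str | None = None
    subsequent_ids: frozenset[str] = frozenset()
    assignments: tuple[DescriptorAssignment, ...] = ()
    meta: RecordMeta = field(default_factory=RecordMeta)


class Severity(str, enum.Enum):
    PASS = "PASS"
    WARN = "WARN"
    FAIL = "FAIL"


@dataclass(frozen=True)
class ValidationIssue:
    severity: Severity
    reason: str
    concept_id: str | None = None
    detail: str = ""


@dataclass
class ValidationReport:
    unit_id: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def failures(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity is Severity.FAIL]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity is Severity.WARN]

    @property
    def ok(self) -> bool:
        return not self.failures


def _is_number(text: str) -> bool:
    try:
        float(text)
    except (TypeError, ValueError):
        return False
    return True


def validate_assignment(
    assignment: DescriptorAssignment,
    manifest: SchemaManifest,
    *,
    sequence_alphabet: frozenset[str] = SEQUENCE_ALPHABET,
) -> ValidationIssue:
    """Validate one assignment against its concept's data type.

    Returns a single :class:`ValidationIssue`; an unresolvable concept id
    raises :class:`RecordReferenceError` (a broken reference is not a data
    failure).  Reason codes on non-PASS results:
    ``value-not-in-vocabulary``, ``other-value-without-supplement``,
    ``non-numeric``, ``invalid-sequence-characters``, ``empty-value``.
    """
    concept = manifest.concepts.get(assignment.concept_id)
    if concept is None:
        raise RecordReferenceError(
            f"assignment references unknown concept {assignment.concept_id!r}")
    cid = concept.concept_id
    if assignment.value is None or assignment.value == "":
        return ValidationIssue(Severity.FAIL, "empty-value", cid)

    if concept.is_categorical:
        value = concept.value_by_label(assignment.value)
        if value is None:
            return ValidationIssue(
                Severity.FAIL, "value-not-in-vocabulary", cid,
                f"{assignment.value!r} not among predefined values")
        if value.is_other_value and not assignment.supplement:
            return ValidationIssue(
                Severity.WARN, "other-value-without-supplement", cid,
                f"{OTHER_VALUE_LABEL!r} should carry the original wording")
        return ValidationIssue(Severity.PASS, "ok", cid)

    if concept.data_type is DataTypeToken.QUANTITATIVE:
        if not _is_number(assignment.value):
            return ValidationIssue(Severity.FAIL, "non-numeric", cid,
                                   f"{assignment.value!r} is not a number")
        return ValidationIssue(Severity.PASS, "ok", cid)

    if concept.data_type is DataTypeToken.SEQUENCE:
        bad = {ch for ch in assignment.value.upper() if ch not in sequence_alphabet}
        if bad:
            return ValidationIssue(Severity.FAIL, "invalid-sequence-characters", cid,
                                   "outside alphabet: " + "".join(sorted(bad)))
        return ValidationIssue(Severity.PASS, "ok", cid)

    return ValidationIssue(Severity.PASS, "ok", cid)  # TEXT


def validate_record(record: UnitRecord, manifest: SchemaManifest) -> ValidationReport:
    """Validate a whole record: record-level checks plus every assignment.

    Record-level reason codes: ``self-loop`` (unit id among its own
    preceding/subsequent ids), ``empty-unit-id``, ``unresolved-concept``
    (an assignment referencing a concept absent from the manifest).
    """
    report = ValidationReport(unit_id=record.unit_id)
    if not record.unit_id:
        report.issues.append(ValidationIssue(Severity.FAIL, "empty-unit-id"))
    if record.unit_id in record.preceding_ids or record.unit_id in record.subsequent_ids:
        report.issues.append(ValidationIssue(
            Severity.FAIL, "self-loop", detail=record.unit_id))
    for a in record.assignments:
        try:
            issue = validate_assignment(a, manifest)
        except RecordReferenceError:
            issue = ValidationIssue(Severity.FAIL, "unresolved-concept", a.concept_id)
        if issue.severity is not Severity.PASS:
            report.issues.append(issue)
    return report


# ---------------------------------------------------------------------------
# CSV round-trip


def format_cell(concept: Concept, assignment: DescriptorAssignment) -> str:
    """Encode an assignment payload as one CSV cell.

    * categorical: ``label`` or ``label | supplement``;
    * quantitative: ``number`` or ``number unit`` (first token numeric);
    * text / sequence: the raw payload.
    """
    if concept.is_categorical and assignment.supplement:
        return assignment.value + _SUPPLEMENT_SEP + assignment.supplement
    if concept.data_type is DataTypeToken.QUANTITATIVE and assignment.unit_of_measure:
        return f"{assignment.value} {assignment.unit_of_measure}"
    return assignment.value


def parse_cell(concept: Concept, cell: str) -> DescriptorAssignment:
    """Inverse of :func:`format_cell`."""
    if concept.is_categorical and _SUPPLEMENT_SEP in cell:
        value, supplement = cell.split(_SUPPLEMENT_SEP, 1)
        return DescriptorAssignment(concept.concept_id, value, supplement=supplement)
    if concept.data_type is DataTypeToken.QUANTITATIVE:
        head, _, tail = cell.partition(" ")
        if tail:
            return DescriptorAssignment(concept.concept_id, head, unit_of_measure=tail)
    return DescriptorAssignment(concept.concept_id, cell)


def _strip_index_suffix(header: str) -> str:
    base, sep, idx = header.rpartition(" #")
    if sep and idx.isdigit():
        return base
    return header


def _split_ids(cell: str) -> frozenset[str]:
    return frozenset(p for p in (s.strip() for s in cell.split(_LIST_SEP)) if p)


def read_records(source, manifest: SchemaManifest) -> list[UnitRecord]:
    """Read a record table (CSV path, file object or text).

    Unknown concept columns raise :class:`UnknownColumnWarning` warnings
    and are otherwise ignored; a missing ``unit_id`` column or a duplicate
    unit id is a :class:`RecordFormatError`.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and (
        isinstance(source, os.PathLike) or ("\n" not in str(source) and os.path.exists(source))
    ):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            text = fh.read()
    else:
        text = str(source)

    reader = csv.reader(io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise RecordFormatError("record table has no header row")
    if "unit_id" not in header:
        raise RecordFormatError("record table lacks the required 'unit_id' column")

    by_name = {c.name: c for c in manifest.concepts.values()}
    columns: list[tuple[str, Concept | None]] = []
    for h in header:
        if h in RESERVED_COLUMNS:
            columns.append((h, None))
            continue
        concept = by_name.get(_strip_index_suffix(h))
        if concept is None:
            warnings.warn(f"unknown column {h!r} ignored", UnknownColumnWarning,
                          stacklevel=2)
        columns.append((h, concept))

    records: list[UnitRecord] = []
    seen: set[str] = set()
    for row in reader:
        if not any(cell.strip() for cell in row):
            continue
        cells = dict()
        assignments: list[DescriptorAssignment] = []
        for (h, concept), cell in zip(columns, row):
            if h in RESERVED_COLUMNS:
                cells[h] = cell
            elif concept is not None and cell != "":
                assignments.append(parse_cell(concept, cell))
        unit_id = cells.get("unit_id", "").strip()
        if not unit_id:
            raise RecordFormatError("row with empty unit_id")
        if unit_id in seen:
            raise RecordFormatError(f"duplicate unit_id {unit_id!r}")
        seen.add(unit_id)
        try:
            elementary = ElementaryDomain(cells.get("unit_domain_elementary", ""))
            operation = OperationDomain(cells.get("unit_operation_domain", ""))
        except ValueError as exc:
            raise RecordFormatError(
                f"record {unit_id!r} has invalid domain value: {exc}") from exc
        records.append(UnitRecord(
            unit_id=unit_id,
            elementary_domain=elementary,
            operation_domain=operation,
            preceding_ids=_split_ids(cells.get("unit_id_preceding", "")),
            origin_id=cells.get("unit_id_origin", "").strip() or None,
            subsequent_ids=_split_ids(cells.get("unit_id_subsequent", "")),
            assignments=tuple(assignments),
            meta=RecordMeta(
                created=cells.get("unit_record_created", "").strip() or None,
                agent=cells.get("unit_record_agent", "").strip() or None,
            ),
        ))
    return records


def write_records(
    records: list[UnitRecord],
    manifest: SchemaManifest,
    path: str | os.PathLike | None = None,
) -> str:
    """Write a canonical record table; returns the CSV text.

    Concept columns appear in manifest order, restricted to concepts that
    are actually assigned; multi-valued assignments repeat the column with
    an ``' #N'`` index suffix.  ``write_records`` then ``read_records`` is
    the identity on the record list.
    """
    used: dict[str, int] = {}
    for r in records:
        per_record: dict[str, int] = {}
        for a in r.assignments:
            per_record[a.concept_id] = per_record.get(a.concept_id, 0) + 1
        for cid, n in per_record.items():
            used[cid] = max(used.get(cid, 0), n)

    concept_cols: list[tuple[str, str, int]] = []  # (header, concept_id, occurrence)
    for cid, concept in manifest.concepts.items():
        for occurrence in range(used.get(cid, 0)):
            header = concept.name if occurrence == 0 else f"{concept.name} #{occurrence + 1}"
            concept_cols.append((header, cid, occurrence))

    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(list(RESERVED_COLUMNS) + [h for h, _, _ in concept_cols])
    for r in records:
        row = [
            r.unit_id,
            _LIST_SEP.join(sorted(r.preceding_ids)),
            r.origin_id or "",
            _LIST_SEP.join(sorted(r.subsequent_ids)),
            r.elementary_domain.value,
            r.operation_domain.value,
            r.meta.created or "",
            r.meta.agent or "",
        ]
        per_concept: dict[str, list[DescriptorAssignment]] = {}
        for a in r.assignments:
            per_concept.setdefault(a.concept_id, []).append(a)
        for _, cid, occurrence in concept_cols:
            group = per_concept.get(cid, [])
            if occurrence < len(group):
                row.append(format_cell(manifest.concepts[cid], group[occurrence]))
            else:
                row.append("")
        writer.writerow(row)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text
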