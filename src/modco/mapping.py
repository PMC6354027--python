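"""Cross-schema record mapping under SKOS-typed correspondences.

A mapping table relates concepts of a source schema to concepts of a
target schema, each correspondence typed with a SKOS mapping property
(exact / close / broad / narrow / related match), plus value-level
correspondences for categorical vocabularies.  Categorical target
vocabularies constrain mapping: a source value without a value-level
correspondence cannot simply be copied.  Three fallback policies handle
such values:

* ``other_value`` — assign the target concept's ``other value`` state and
  carry the original wording of the source value as the free-text
  supplement;
* ``whole_text`` — write the original wording to the target concept as a
  whole, treated as text;
* ``drop`` — omit the assignment.

Only exact and close correspondences trigger value substitution by
default; broad/narrow/related ones are carried as metadata and need
``allow_inexact=True`` to substitute.  Every mapped record satisfies the
conservation law mapped + fallback + dropped = total assignments, and the
mapping never invents values absent from the target vocabulary.

Tables are CSV with a 5-column layout
``source_concept,source_value,target_concept,target_value,match_type``:
concept rows leave the value columns empty, value rows may leave
``match_type`` empty.
"""

from __future__ import annotations

import csv
import enum
import io
import os
from dataclasses import dataclass, field

from .errors import MappingError
from .records import DescriptorAssignment, UnitRecord
from .schema import SchemaManifest
from .vocab import MatchType, OTHER_VALUE_LABEL

__all__ = [
    "FallbackPolicy",
    "ConceptMap",
    "MappingTable",
    "MappingReport",
    "map_record",
    "coverage_report",
    "identity_table",
    "read_mapping_table",
    "write_mapping_table",
]

#: Correspondence types that substitute values without an explicit opt-in.
DEFAULT_SUBSTITUTING = frozenset({MatchType.EXACT, MatchType.CLOSE})


class FallbackPolicy(str, enum.Enum):
    OTHER_VALUE = "other_value"
    WHOLE_TEXT = "whole_text"
    DROP = "drop"


@dataclass(frozen=True)
class ConceptMap:
    source_concept: str
    target_concept: str
    match_type: MatchType


@dataclass
class MappingTable:
    concept_maps: dict[str, ConceptMap] = field(default_factory=dict)
    value_maps: dict[tuple[str, str], str] = field(default_factory=dict)
    policy: FallbackPolicy = FallbackPolicy.OTHER_VALUE

    def add_concept(self, source: str, target: str,
                    match: MatchType = MatchType.EXACT) -> None:
        self.concept_maps[source] = ConceptMap(source, target, match)

    def add_value(self, source_concept: str, source_value: str,
                  target_value: str) -> None:
        key = (source_concept, source_value.lower())
        if key in self.value_maps and self.value_maps[key] != target_value:
            raise MappingError(
                f"conflicting targets for value {source_value!r} of "
                f"{source_concept!r}")
        self.value_maps[key] = target_value

    def check(self) -> None:
        """Table-level invariants; raises :class:`MappingError`."""
        for concept_id, _ in self.value_maps:
            if concept_id not in self.concept_maps:
                raise MappingError(
                    f"value map for {concept_id!r} lacks a concept map")


@dataclass
class MappingReport:
    """Outcome counts and fallback wordings of one mapping run."""

    mapped: dict[str, int] = field(default_factory=dict)
    fallback: dict[str, int] = field(default_factory=dict)
    dropped: dict[str, int] = field(default_factory=dict)
    #: (source concept, original wording) per fallback, in record order
    fallback_wordings: list[tuple[str, str]] = field(default_factory=list)
    drop_reasons: list[tuple[str, str]] = field(default_factory=list)

    def _bump(self, bucket: dict[str, int], concept_id: str) -> None:
        bucket[concept_id] = bucket.get(concept_id, 0) + 1

    @property
    def n_mapped(self) -> int:
        return sum(self.mapped.values())

    @property
    def n_fallback(self) -> int:
        return sum(self.fallback.values())

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())

    @property
    def total(self) -> int:
        return self.n_mapped + self.n_fallback + self.n_dropped


def map_record(
    record: UnitRecord,
    table: MappingTable,
    target: SchemaManifest,
    *,
    policy: FallbackPolicy | None = None,
    allow_inexact: bool = False,
) -> tuple[UnitRecord, MappingReport]:
    """Rewrite a record's assignments from source onto target schema.

    Identifier links and domains pass through unchanged.  Raises
    :class:`MappingError` when a correspondence points at a concept or
    value missing from the target manifest (the mapping must never invent
    target vocabulary).
    """
    table.check()
    policy = policy or table.policy
    report = MappingReport()
    out: list[DescriptorAssignment] = []

    for a in record.assignments:
        cm = table.concept_maps.get(a.concept_id)
        if cm is None:
            report._bump(report.dropped, a.concept_id)
            report.drop_reasons.append((a.concept_id, "no-concept-map"))
            continue
        target_concept = target.concepts.get(cm.target_concept)
        if target_concept is None:
            raise MappingError(
                f"concept map {a.concept_id!r} -> {cm.target_concept!r} "
                f"points outside the target schema")

        if not target_concept.is_categorical:
            # free payloads transfer as a whole
            out.append(DescriptorAssignment(
                target_concept.concept_id, a.value,
                supplement=a.supplement, unit_of_measure=a.unit_of_measure))
            report._bump(report.mapped, a.concept_id)
            continue

        mapped_label = None
        if cm.match_type in DEFAULT_SUBSTITUTING or allow_inexact:
            mapped_label = table.value_maps.get((a.concept_id, a.value.lower()))
        if mapped_label is not None:
            target_value = target_concept.value_by_label(mapped_label)
            if target_value is None:
                raise MappingError(
                    f"value map {a.value!r} -> {mapped_label!r} is not a "
                    f"predefined value of {target_concept.concept_id!r}")
            out.append(DescriptorAssignment(
                target_concept.concept_id, target_value.label,
                supplement=a.supplement))
            report._bump(report.mapped, a.concept_id)
            continue

        # unmapped categorical value: apply the fallback policy
        if policy is FallbackPolicy.OTHER_VALUE:
            other = target_concept.other_value
            if other is None:
                report._bump(report.dropped, a.concept_id)
                report.drop_reasons.append((a.concept_id, "no-other-value-state"))
                continue
            out.append(DescriptorAssignment(
                target_concept.concept_id, OTHER_VALUE_LABEL, supplement=a.value))
            report._bump(report.fallback, a.concept_id)
            report.fallback_wordings.append((a.concept_id, a.value))
        elif policy is FallbackPolicy.WHOLE_TEXT:
            out.append(DescriptorAssignment(
                target_concept.concept_id, a.value, supplement=a.supplement))
            report._bump(report.fallback, a.concept_id)
            report.fallback_wordings.append((a.concept_id, a.value))
        else:  # DROP
            report._bump(report.dropped, a.concept_id)
            report.drop_reasons.append((a.concept_id, "no-value-map"))

    mapped = UnitRecord(
        unit_id=record.unit_id,
        elementary_domain=record.elementary_domain,
        operation_domain=record.operation_domain,
        preceding_ids=record.preceding_ids,
        origin_id=record.origin_id,
        subsequent_ids=record.subsequent_ids,
        assignments=tuple(out),
        meta=record.meta,
    )
    return mapped, report


@dataclass(frozen=True)
class CoverageStats:
    """Deterministic coverage of a table over a source schema."""

    #: collection id -> (mapped concepts, total member concepts)
    per_collection: dict[str, tuple[int, int]]
    #: concept id -> fraction of its values with a value map (categorical only)
    value_coverage: dict[str, float]
    n_mapped_concepts: int
    n_source_concepts: int

    @property
    def concept_coverage(self) -> float:
        if not self.n_source_concepts:
            return 0.0
        return self.n_mapped_concepts / self.n_source_concepts


def coverage_report(table: MappingTable, source: SchemaManifest,
                    target: SchemaManifest) -> CoverageStats:
    """Per-collection and per-concept coverage of a mapping table."""
    table.check()
    for cm in table.concept_maps.values():
        if cm.source_concept not in source.concepts:
            raise MappingError(f"unknown source concept {cm.source_concept!r}")
        if cm.target_concept not in target.concepts:
            raise MappingError(f"unknown target concept {cm.target_concept!r}")

    mapped_ids = set(table.concept_maps)
    per_collection: dict[str, tuple[int, int]] = {}
    for cid in sorted(source.collections):
        members = source.members(cid)
        per_collection[cid] = (len(members & mapped_ids), len(members))

    value_coverage: dict[str, float] = {}
    for cid in sorted(source.concepts):
        concept = source.concepts[cid]
        if not concept.is_categorical or not concept.values:
            continue
        hit = sum(1 for v in concept.values
                  if (cid, v.label.lower()) in table.value_maps)
        value_coverage[cid] = hit / len(concept.values)

    return CoverageStats(
        per_collection=per_collection,
        value_coverage=value_coverage,
        n_mapped_concepts=len(mapped_ids & set(source.concepts)),
        n_source_concepts=len(source.concepts),
    )


def identity_table(manifest: SchemaManifest) -> MappingTable:
    """Exact self-mapping of a manifest (useful as a lossless baseline)."""
    table = MappingTable()
    for cid, concept in manifest.concepts.items():
        table.add_concept(cid, cid, MatchType.EXACT)
        for v in concept.values:
            table.add_value(cid, v.label, v.label)
    return table


def read_mapping_table(source, *,
                       policy: FallbackPolicy = FallbackPolicy.OTHER_VALUE
                       ) -> MappingTable:
    """Read the 5-column CSV layout described in the module docstring."""
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, (str, os.PathLike)) and (
        isinstance(source, os.PathLike) or ("\n" not in str(source) and os.path.exists(source))
    ):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            text = fh.read()
    else:
        text = str(source)
    reader = csv.DictReader(io.StringIO(text))
    required = {"source_concept", "source_value", "target_concept", "target_value",
                "match_type"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise MappingError(
            "mapping table must have columns "
            "source_concept,source_value,target_concept,target_value,match_type")
    table = MappingTable(policy=policy)
    for row in reader:
        src = (row["source_concept"] or "").strip()
        if not src:
            continue
        sval = (row["source_value"] or "").strip()
        if sval:
            table.add_value(src, sval, (row["target_value"] or "").strip())
        else:
            match = (row["match_type"] or "exact").strip() or "exact"
            try:
                mt = MatchType(match)
            except ValueError:
                raise MappingError(f"unknown match type {match!r}")
            table.add_concept(src, (row["target_concept"] or "").strip(), mt)
    table.check()
    return table


def write_mapping_table(table: MappingTable,
                        path: str | os.PathLike | None = None) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["source_concept", "source_value", "target_concept",
                     "target_value", "match_type"])
    for src in sorted(table.concept_maps):
        cm = table.concept_maps[src]
        writer.writerow([src, "", cm.target_concept, "", cm.match_type.value])
    for (src, sval) in sorted(table.value_maps):
        writer.writerow([src, sval, table.concept_maps[src].target_concept,
                         table.value_maps[(src, sval)], ""])
    text = buf.getvalue()
    if path is not None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(text)
    return text
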