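"""Deterministic generators for schema manifests and workflow record sets.

Everything here is pure in ``(spec, seed)``: the same inputs produce
byte-identical manifests and record sets, so generated data can serve as
reproducible test fixtures.  Generated concept names obey the multipartite
naming grammar (numbered core elements such as ``sample attribute 017``
cannot collide with registry tokens), and generated data always passes its
own validation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, replace
from typing import Mapping

from .errors import GeneratorSpecError
from .naming import ParsedName, compose_concept_name, parse_concept_name
from .records import DescriptorAssignment, RecordMeta, UnitRecord
from .schema import (
    Concept,
    ConceptCollection,
    ConceptValue,
    SchemaManifest,
    page_slug,
)
from .vocab import (
    DataTypeToken,
    ElementaryDomain,
    OperationDomain,
    OTHER_VALUE_LABEL,
)

__all__ = [
    "CollectionPlan",
    "ManifestSpec",
    "generate_manifest",
    "generate_gbol2_workflow",
    "DEFAULT_NAMESPACE",
]

DEFAULT_NAMESPACE = "http://www.mod-co.net/wiki/modco:"

#: Noun phrases for placeholder core elements; the numeric suffix keeps
#: names unique and grammar-safe (no registered token ends in digits).
_CORE_NOUNS = (
    "sample attribute",
    "process step detail",
    "analysis parameter",
    "object trait",
    "storage condition",
    "document reference",
)


@dataclass(frozen=True)
class CollectionPlan:
    """Plan for one collection (tree or subtree) of a generated manifest.

    ``selector`` restricts the membership pool: ``None`` samples from all
    concepts, ``"level"`` takes every concept at ``level`` (hierarchy
    partition), ``"elementary:physical"`` / ``"operation:measurement"`` /
    ``"property:URI"`` select by naming segment.  ``preset`` lists concept
    ids (typically exemplars) that are members regardless of the selector
    and count toward ``n_members``.
    """

    collection_id: str
    label: str
    parent: str | None = None
    role: str | None = None
    level: int | None = None
    n_members: int | None = None
    selector: str | None = None
    preset: tuple[str, ...] = ()


@dataclass(frozen=True)
class ManifestSpec:
    """Counts and structure of a manifest to generate.

    ``n_by_data_type`` / ``n_by_level`` cover the *placeholder* concepts
    only; ``exemplars`` are taken as given and add on top.  When
    ``n_values_total`` is set it fixes the total number of predefined
    values across the whole manifest (exemplar values included) and the
    generator distributes values as evenly as possible; otherwise each
    categorical placeholder receives 2–8 regular values plus the
    ``other value`` fallback state.

    Optional marginals (``elementary_counts`` etc., again placeholders
    only) pin how many names carry each domain/property token; ``None``
    keys mean "segment absent".
    """

    n_by_data_type: Mapping[DataTypeToken, int]
    n_by_level: Mapping[int, int]
    version: str = "1.0"
    namespace_base: str = DEFAULT_NAMESPACE
    n_values_total: int | None = None
    elementary_counts: Mapping[ElementaryDomain | None, int] | None = None
    operation_counts: Mapping[OperationDomain | None, int] | None = None
    property_counts: Mapping[str | None, int] | None = None
    collections: tuple[CollectionPlan, ...] = ()
    exemplars: tuple[Concept, ...] = ()

    @property
    def n_placeholders(self) -> int:
        return sum(self.n_by_data_type.values())


def _expand_deck(counts: Mapping, total: int, what: str, rng: random.Random) -> list:
    deck: list = []
    for key in counts:
        n = counts[key]
        if n < 0:
            raise GeneratorSpecError(f"negative count for {what} {key!r}")
        deck.extend([key] * n)
    if len(deck) != total:
        raise GeneratorSpecError(
            f"{what} counts sum to {len(deck)}, expected {total}")
    rng.shuffle(deck)
    return deck


def _value_counts(spec: ManifestSpec, n_categorical: int, rng: random.Random) -> list[int]:
    """Number of values (incl. 'other value') per categorical placeholder."""
    if n_categorical == 0:
        return []
    if spec.n_values_total is None:
        return [rng.randint(2, 8) + 1 for _ in range(n_categorical)]
    remaining = spec.n_values_total - sum(len(e.values) for e in spec.exemplars)
    if remaining < n_categorical * 2:
        raise GeneratorSpecError("n_values_total too small for categorical concepts")
    base, extra = divmod(remaining, n_categorical)
    return [base + 1 if i < extra else base for i in range(n_categorical)]


def generate_manifest(spec: ManifestSpec, seed: int) -> SchemaManifest:
    """Generate a manifest realizing ``spec``; deterministic in the seed."""
    total = spec.n_placeholders
    if sum(spec.n_by_level.values()) != total:
        raise GeneratorSpecError(
            f"per-level counts sum to {sum(spec.n_by_level.values())}, "
            f"expected {total}")

    rng = random.Random(seed)
    dtype_deck = _expand_deck(spec.n_by_data_type, total, "data type", rng)
    level_deck = _expand_deck(spec.n_by_level, total, "level", rng)
    if spec.elementary_counts is not None:
        elem_deck = _expand_deck(spec.elementary_counts, total, "elementary domain", rng)
    else:
        elem_deck = [rng.choice([ElementaryDomain.PHYSICAL, ElementaryDomain.DIGITAL, None])
                     for _ in range(total)]
    if spec.operation_counts is not None:
        op_deck = _expand_deck(spec.operation_counts, total, "operation domain", rng)
    else:
        op_deck = [rng.choice(list(OperationDomain) + [None]) for _ in range(total)]
    if spec.property_counts is not None:
        prop_deck = _expand_deck(spec.property_counts, total, "property", rng)
    else:
        prop_deck = [rng.choice(["name", "ID", "URI", None, None, None])
                     for _ in range(total)]

    manifest = SchemaManifest(version=spec.version, namespace_base=spec.namespace_base)
    segments: dict[str, tuple] = {}  # concept_id -> (elem, op, prop) for selectors

    for exemplar in spec.exemplars:
        concept = replace(
            exemplar,
            uri=exemplar.uri or spec.namespace_base + page_slug(exemplar.name),
        )
        manifest.concepts[concept.concept_id] = concept
        parsed = parse_concept_name(
            concept.name, manifest.registries,
            sequence=concept.data_type is DataTypeToken.SEQUENCE)
        segments[concept.concept_id] = (
            parsed.elementary_domain, parsed.operation_domain, parsed.property)

    n_categorical = sum(
        1 for t in dtype_deck
        if t in (DataTypeToken.CATEGORICAL, DataTypeToken.CATEGORICAL_PLUS_TEXT))
    value_counts = _value_counts(spec, n_categorical, rng)

    width = max(4, len(str(total + len(spec.exemplars))))
    cat_index = 0
    for i in range(total):
        dtype = dtype_deck[i]
        parsed = ParsedName(
            elementary_domain=elem_deck[i],
            operation_domain=op_deck[i],
            core_element=f"{_CORE_NOUNS[i % len(_CORE_NOUNS)]} {i:03d}",
            property=prop_deck[i],
            data_type=dtype,
        )
        name = compose_concept_name(parsed)
        cid = f"c{i + 1:0{width}d}"
        values: tuple[ConceptValue, ...] = ()
        if dtype in (DataTypeToken.CATEGORICAL, DataTypeToken.CATEGORICAL_PLUS_TEXT):
            n_vals = value_counts[cat_index]
            cat_index += 1
            regular = tuple(
                ConceptValue(value_id=f"v{j + 1}", label=f"state {j + 1:02d}")
                for j in range(n_vals - 1))
            values = regular + (
                ConceptValue(value_id=f"v{n_vals}", label=OTHER_VALUE_LABEL,
                             is_other_value=True),)
        manifest.concepts[cid] = Concept(
            concept_id=cid,
            name=name,
            data_type=dtype,
            hierarchy_level=level_deck[i],
            values=values,
            uri=spec.namespace_base + page_slug(name),
        )
        segments[cid] = (elem_deck[i], op_deck[i], prop_deck[i])

    _apply_collections(manifest, spec, segments, rng)
    return manifest


def _eligible(manifest: SchemaManifest, segments: dict, plan: CollectionPlan) -> list[str]:
    if plan.selector is None:
        return sorted(manifest.concepts)
    if plan.selector == "level":
        return sorted(cid for cid, c in manifest.concepts.items()
                      if c.hierarchy_level == plan.level)
    kind, _, token = plan.selector.partition(":")
    index = {"elementary": 0, "operation": 1, "property": 2}.get(kind)
    if index is None:
        raise GeneratorSpecError(f"unknown selector {plan.selector!r}")
    return sorted(
        cid for cid, seg in segments.items()
        if seg[index] is not None and (
            seg[index].value if hasattr(seg[index], "value") else seg[index]) == token)


def _apply_collections(manifest: SchemaManifest, spec: ManifestSpec,
                       segments: dict, rng: random.Random) -> None:
    membership: dict[str, list[str]] = {cid: [] for cid in manifest.concepts}
    for plan in spec.collections:
        manifest.collections[plan.collection_id] = ConceptCollection(
            collection_id=plan.collection_id,
            label=plan.label,
            parent=plan.parent,
            role=plan.role,
            level=plan.level,
        )
        members = list(plan.preset)
        pool = [cid for cid in _eligible(manifest, segments, plan)
                if cid not in plan.preset]
        if plan.n_members is None:
            members.extend(pool)
        else:
            needed = plan.n_members - len(members)
            if needed < 0 or needed > len(pool):
                raise GeneratorSpecError(
                    f"collection {plan.collection_id!r} wants {plan.n_members} "
                    f"members but pool offers {len(pool)} (+{len(members)} preset)")
            members.extend(sorted(rng.sample(pool, needed)))
        for cid in members:
            if cid not in membership:
                raise GeneratorSpecError(
                    f"collection {plan.collection_id!r} presets unknown concept {cid!r}")
            membership[cid].append(plan.collection_id)
    for cid, cols in membership.items():
        manifest.concepts[cid].collections = tuple(sorted(cols))


# ---------------------------------------------------------------------------
# GBOL-2-style workflow record set


def _first_concept(manifest: SchemaManifest, dtype: DataTypeToken) -> Concept:
    for cid in sorted(manifest.concepts):
        if manifest.concepts[cid].data_type is dtype:
            return manifest.concepts[cid]
    raise GeneratorSpecError(f"manifest has no {dtype.value} concept")


def generate_gbol2_workflow(
    seed: int,
    manifest: SchemaManifest | None = None,
) -> list[UnitRecord]:
    """Record set emulating a four-segment fungal microbiome barcoding run.

    The workflow runs from field sampling of fruit-tree leaves through
    total nucleic-acid extraction and marker-gene amplification with
    amplicon pooling to HTS (MiSeq) read-data generation:

    1. physical field sample, collected (transformation) and moved to the
       lab (transaction);
    2. physical nucleic-acid extract (transformation) with a digital
       concentration measurement child;
    3. physical amplicons, two parallel aliquots pooled into one unit
       (the pool has in-degree 2);
    4. the pool loaded as sequencing library (transformation), the digital
       HTS read-data unit (measurement) and its archival (transaction).

    All records validate against the manifest (default: the packaged
    fixture) and their identifier links form a DAG rooted at the field
    sample.  Deterministic in the seed.
    """
    if manifest is None:
        from .fixture import fixture_manifest
        manifest = fixture_manifest()
    rng = random.Random(seed)

    def concept(name: str) -> Concept:
        c = manifest.concept_by_name(name)
        if c is None:
            raise GeneratorSpecError(f"manifest lacks expected concept {name!r}")
        return c

    device = concept("unit digital measurement device URI <string>")
    primer = concept("unit physical transformation community genomic analysis "
                     "sequencing library index primer name <string>")
    protocol_mod = concept("unit physical transformation protocol modification <category>")
    quant = _first_concept(manifest, DataTypeToken.QUANTITATIVE)
    seq = _first_concept(manifest, DataTypeToken.SEQUENCE)
    notes = _first_concept(manifest, DataTypeToken.TEXT)

    meta = RecordMeta(created="2018-09-12T09:30:00", agent="field team FT-02")
    origin = "GBOL2-SAMPLE-001"
    concentration = f"{rng.uniform(5.0, 80.0):.1f}"
    read = "".join(rng.choice("ACGT") for _ in range(rng.randint(20, 60)))

    def rec(unit_id, elem, op, preceding=(), subsequent=(), assignments=(),
            is_root=False):
        return UnitRecord(
            unit_id=unit_id,
            elementary_domain=elem,
            operation_domain=op,
            preceding_ids=frozenset(preceding),
            origin_id=None if is_root else origin,
            subsequent_ids=frozenset(subsequent),
            assignments=tuple(assignments),
            meta=meta,
        )

    P, D = ElementaryDomain.PHYSICAL, ElementaryDomain.DIGITAL
    T, M, X = (OperationDomain.TRANSFORMATION, OperationDomain.MEASUREMENT,
               OperationDomain.TRANSACTION)
    return [
        rec(origin, P, T, is_root=True, assignments=[
            DescriptorAssignment(notes.concept_id,
                                 "leaf sample, rosaceous fruit tree orchard"),
        ]),
        rec("GBOL2-SAMPLE-DEP-001", P, X, preceding=[origin]),
        rec("GBOL2-EXTRACT-001", P, T, preceding=["GBOL2-SAMPLE-DEP-001"]),
        rec("GBOL2-EXTRACT-QC-001", D, M, preceding=["GBOL2-EXTRACT-001"],
            assignments=[
                DescriptorAssignment(quant.concept_id, concentration,
                                     unit_of_measure="ng/ul"),
                DescriptorAssignment(device.concept_id,
                                     "http://example.org/devices/fluorometer-01"),
            ]),
        rec("GBOL2-AMPLICON-001", P, T, preceding=["GBOL2-EXTRACT-001"],
            subsequent=["GBOL2-POOL-001"],
            assignments=[DescriptorAssignment(primer.concept_id, "ITS1F")]),
        rec("GBOL2-AMPLICON-002", P, T, preceding=["GBOL2-EXTRACT-001"],
            subsequent=["GBOL2-POOL-001"],
            assignments=[DescriptorAssignment(primer.concept_id, "ITS4")]),
        rec("GBOL2-POOL-001", P, T,
            preceding=["GBOL2-AMPLICON-001", "GBOL2-AMPLICON-002"],
            assignments=[
                DescriptorAssignment(protocol_mod.concept_id, "property parameters"),
            ]),
        rec("GBOL2-LIB-001", P, T, preceding=["GBOL2-POOL-001"]),
        rec("GBOL2-READS-001", D, M, preceding=["GBOL2-LIB-001"],
            assignments=[
                DescriptorAssignment(seq.concept_id, read),
                DescriptorAssignment(device.concept_id,
                                     "http://example.org/devices/miseq-01"),
            ]),
        rec("GBOL2-READS-ARCH-001", D, X, preceding=["GBOL2-READS-001"]),
    ]
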