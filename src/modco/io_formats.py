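"""Serializers for the schema's publication representations.

Three representation families are supported, mirroring how descriptor
schemas of this kind are published:

* **SDD-structured XML** — a documented *minimal dialect* in the spirit of
  the TDWG "Structure of Descriptive Data" family (descriptors with state
  lists, descriptions for records), not a certified SDD 1.1
  implementation.  :func:`write_sdd_xml` / :func:`read_sdd_xml` round-trip
  a manifest plus optional records up to canonical ordering; foreign
  elements are ignored with a warning.
* **XSD** — a generated XML Schema declaring one element per concept
  (text/sequence → ``xs:string``, quantitative → ``xs:decimal``,
  categorical → an enumeration of the value labels) against which record
  documents produced by :func:`write_record_xml` validate.
* **RDF** — one subject per concept, value and collection under the
  manifest's stable-URI namespace (wiki-style page slugs: spaces to
  underscores, reserved characters percent-encoded), serialized as Turtle.

All writers are deterministic: identical inputs yield byte-identical
output (fixed element ordering, no timestamps unless injected).
"""

from __future__ import annotations

import re
import warnings

from lxml import etree
from rdflib import Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.namespace import OWL, SKOS, XSD

from .errors import DialectError
from .records import DescriptorAssignment, RecordMeta, UnitRecord
from .schema import (
    Concept,
    ConceptCollection,
    ConceptValue,
    SchemaManifest,
    page_slug,
)
from .vocab import DataTypeToken, ElementaryDomain, OperationDomain

__all__ = [
    "SDD_FORMAT_TAG",
    "write_sdd_xml",
    "read_sdd_xml",
    "write_xsd",
    "write_record_xml",
    "compile_xsd",
    "validate_record_xml",
    "write_rdf",
    "write_eml_stub",
    "xml_name",
    "ForeignElementWarning",
]

SDD_FORMAT_TAG = "modco-sdd/1"

#: Predicate vocabulary for the RDF export (the subjects live under the
#: manifest's own namespace; predicates are package vocabulary).
MT = Namespace("https://w3id.org/modco/terms#")

XS = "http://www.w3.org/2001/XMLSchema"


class ForeignElementWarning(UserWarning):
    """An SDD document contains an element outside the dialect."""


def xml_name(concept_name: str) -> str:
    """Map a concept name onto a valid XML element name (NCName).

    Spaces become underscores; any remaining character outside
    ``[A-Za-z0-9_.-]`` becomes an underscore; a leading non-letter gains
    an ``n_`` prefix.  Distinct concepts mapping to the same element name
    are a hard error (:class:`DialectError`).
    """
    slug = re.sub(r"[^A-Za-z0-9_.\-]", "_", concept_name.replace(" ", "_"))
    if not re.match(r"[A-Za-z_]", slug):
        slug = "n_" + slug
    return slug


# ---------------------------------------------------------------------------
# SDD-structured XML dialect


def _sdd_descriptor(parent: etree._Element, concept: Concept) -> None:
    d = etree.SubElement(parent, "Descriptor", {
        "id": concept.concept_id,
        "name": concept.name,
        "dataType": concept.data_type.value,
        "level": str(concept.hierarchy_level),
        "uri": concept.uri,
    })
    if concept.cardinality is not None:
        d.set("cardinality", concept.cardinality)
    if concept.definition is not None:
        etree.SubElement(d, "Definition").text = concept.definition
    if concept.values:
        states = etree.SubElement(d, "States")
        for v in concept.values:
            s = etree.SubElement(states, "State", {"id": v.value_id, "label": v.label})
            if v.is_other_value:
                s.set("other", "true")
            if v.uri:
                s.set("uri", v.uri)
    if concept.collections:
        cols = etree.SubElement(d, "Collections")
        for cid in sorted(concept.collections):
            etree.SubElement(cols, "CollectionRef", {"ref": cid})


def _sdd_description(parent: etree._Element, record: UnitRecord,
                     manifest: SchemaManifest) -> None:
    attrs = {
        "unitId": record.unit_id,
        "elementaryDomain": record.elementary_domain.value,
        "operationDomain": record.operation_domain.value,
    }
    if record.preceding_ids:
        attrs["precedingIds"] = ";".join(sorted(record.preceding_ids))
    if record.origin_id:
        attrs["originId"] = record.origin_id
    if record.subsequent_ids:
        attrs["subsequentIds"] = ";".join(sorted(record.subsequent_ids))
    if record.meta.created:
        attrs["created"] = record.meta.created
    if record.meta.agent:
        attrs["agent"] = record.meta.agent
    desc = etree.SubElement(parent, "Description", attrs)
    for a in record.assignments:
        concept = manifest.concepts.get(a.concept_id)
        if concept is None:
            raise DialectError(f"record {record.unit_id!r} assigns unknown "
                               f"concept {a.concept_id!r}")
        el = etree.SubElement(desc, "Assignment", {"descriptorRef": a.concept_id})
        if concept.is_categorical:
            value = concept.value_by_label(a.value)
            node = etree.SubElement(el, "StateRef")
            if value is not None:
                node.set("ref", value.value_id)
            else:  # out-of-vocabulary payloads survive the round-trip
                node.set("label", a.value)
            if a.supplement:
                etree.SubElement(el, "Supplement").text = a.supplement
        elif concept.data_type is DataTypeToken.QUANTITATIVE:
            node = etree.SubElement(el, "Measure")
            node.text = a.value
            if a.unit_of_measure:
                node.set("unitOfMeasure", a.unit_of_measure)
        elif concept.data_type is DataTypeToken.SEQUENCE:
            etree.SubElement(el, "Sequence").text = a.value
        else:
            etree.SubElement(el, "Text").text = a.value


def write_sdd_xml(
    manifest: SchemaManifest,
    records: list[UnitRecord] | None = None,
) -> bytes:
    """Serialize a manifest (and optionally records) to the SDD dialect."""
    root = etree.Element("ModcoSDD", {
        "format": SDD_FORMAT_TAG,
        "schemaVersion": manifest.version,
        "namespaceBase": manifest.namespace_base,
    })
    reg = etree.SubElement(root, "Registries")
    ops = etree.SubElement(reg, "OperationDomains")
    for token in manifest.registries.operation_domains:
        etree.SubElement(ops, "Token").text = token
    props = etree.SubElement(reg, "Properties")
    for token in manifest.registries.properties:
        etree.SubElement(props, "Token").text = token
    cols = etree.SubElement(root, "Collections")
    for cid in sorted(manifest.collections):
        col = manifest.collections[cid]
        attrs = {"id": cid, "label": col.label}
        if col.parent is not None:
            attrs["parent"] = col.parent
        if col.role is not None:
            attrs["role"] = col.role
        if col.level is not None:
            attrs["level"] = str(col.level)
        etree.SubElement(cols, "Collection", attrs)
    descs = etree.SubElement(root, "Descriptors")
    for cid in sorted(manifest.concepts):
        _sdd_descriptor(descs, manifest.concepts[cid])
    if records is not None:
        body = etree.SubElement(root, "Descriptions")
        for r in records:
            _sdd_description(body, r, manifest)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def _parse_assignment(el: etree._Element, concepts: dict[str, Concept],
                      unit_id: str) -> DescriptorAssignment:
    ref = el.get("descriptorRef", "")
    concept = concepts.get(ref)
    if concept is None:
        raise DialectError(
            f"{_path(el)}: assignment in {unit_id!r} references "
            f"undeclared descriptor {ref!r}")
    value = ""
    supplement = None
    uom = None
    for child in el:
        if child.tag == "StateRef":
            vid = child.get("ref")
            if vid is not None:
                match = [v for v in concept.values if v.value_id == vid]
                if not match:
                    raise DialectError(
                        f"{_path(child)}: state {vid!r} not declared on {ref!r}")
                value = match[0].label
            else:
                value = child.get("label", "")
        elif child.tag == "Supplement":
            supplement = child.text or ""
        elif child.tag in ("Text", "Sequence"):
            value = child.text or ""
        elif child.tag == "Measure":
            value = child.text or ""
            uom = child.get("unitOfMeasure")
        else:
            warnings.warn(f"foreign element {child.tag!r} ignored",
                          ForeignElementWarning, stacklevel=2)
    return DescriptorAssignment(ref, value, supplement=supplement,
                                unit_of_measure=uom)


def _path(el: etree._Element) -> str:
    return el.getroottree().getpath(el)


def read_sdd_xml(doc: bytes | str) -> tuple[SchemaManifest, list[UnitRecord]]:
    """Parse an SDD-dialect document back into manifest + records.

    Inverse of :func:`write_sdd_xml` on canonical documents.  Malformed
    XML raises ``lxml.etree.XMLSyntaxError``; dialect violations raise
    :class:`DialectError` with the element path; foreign elements are
    skipped with :class:`ForeignElementWarning`.
    """
    if isinstance(doc, str):
        doc = doc.encode("utf-8")
    root = etree.fromstring(doc)
    if root.tag != "ModcoSDD":
        raise DialectError(f"/: unexpected root element {root.tag!r}")
    if root.get("format") != SDD_FORMAT_TAG:
        raise DialectError(f"/: unsupported format tag {root.get('format')!r}")

    from .naming import VocabRegistries

    manifest = SchemaManifest(
        version=root.get("schemaVersion", ""),
        namespace_base=root.get("namespaceBase", ""),
    )
    records: list[UnitRecord] = []
    for section in root:
        if section.tag == "Registries":
            ops: list[str] = []
            props: list[str] = []
            for sub in section:
                target = {"OperationDomains": ops, "Properties": props}.get(sub.tag)
                if target is None:
                    warnings.warn(f"foreign element {sub.tag!r} ignored",
                                  ForeignElementWarning, stacklevel=2)
                    continue
                target.extend(t.text or "" for t in sub if t.tag == "Token")
            manifest.registries = VocabRegistries(
                operation_domains=tuple(ops), properties=tuple(props))
        elif section.tag == "Collections":
            for el in section:
                if el.tag != "Collection":
                    warnings.warn(f"foreign element {el.tag!r} ignored",
                                  ForeignElementWarning, stacklevel=2)
                    continue
                level = el.get("level")
                manifest.collections[el.get("id", "")] = ConceptCollection(
                    collection_id=el.get("id", ""),
                    label=el.get("label", ""),
                    parent=el.get("parent"),
                    role=el.get("role"),
                    level=int(level) if level is not None else None,
                )
        elif section.tag == "Descriptors":
            for el in section:
                if el.tag != "Descriptor":
                    warnings.warn(f"foreign element {el.tag!r} ignored",
                                  ForeignElementWarning, stacklevel=2)
                    continue
                values: list[ConceptValue] = []
                collections: list[str] = []
                definition = None
                for child in el:
                    if child.tag == "States":
                        for s in child:
                            if s.tag != "State":
                                continue
                            values.append(ConceptValue(
                                value_id=s.get("id", ""),
                                label=s.get("label", ""),
                                is_other_value=s.get("other") == "true",
                                uri=s.get("uri"),
                            ))
                    elif child.tag == "Collections":
                        collections.extend(
                            c.get("ref", "") for c in child if c.tag == "CollectionRef")
                    elif child.tag == "Definition":
                        definition = child.text
                    else:
                        warnings.warn(f"foreign element {child.tag!r} ignored",
                                      ForeignElementWarning, stacklevel=2)
                try:
                    dtype = DataTypeToken(el.get("dataType", ""))
                except ValueError:
                    raise DialectError(
                        f"{_path(el)}: unknown data type {el.get('dataType')!r}")
                cid = el.get("id", "")
                manifest.concepts[cid] = Concept(
                    concept_id=cid,
                    name=el.get("name", ""),
                    data_type=dtype,
                    hierarchy_level=int(el.get("level", "0")),
                    values=tuple(values),
                    collections=tuple(sorted(collections)),
                    uri=el.get("uri", ""),
                    definition=definition,
                    cardinality=el.get("cardinality"),
                )
        elif section.tag == "Descriptions":
            for el in section:
                if el.tag != "Description":
                    warnings.warn(f"foreign element {el.tag!r} ignored",
                                  ForeignElementWarning, stacklevel=2)
                    continue
                unit_id = el.get("unitId", "")
                assignments = tuple(
                    _parse_assignment(a, manifest.concepts, unit_id)
                    for a in el if a.tag == "Assignment")
                try:
                    elementary = ElementaryDomain(el.get("elementaryDomain", ""))
                    operation = OperationDomain(el.get("operationDomain", ""))
                except ValueError:
                    raise DialectError(f"{_path(el)}: invalid domain attribute")
                records.append(UnitRecord(
                    unit_id=unit_id,
                    elementary_domain=elementary,
                    operation_domain=operation,
                    preceding_ids=frozenset(
                        p for p in (el.get("precedingIds") or "").split(";") if p),
                    origin_id=el.get("originId"),
                    subsequent_ids=frozenset(
                        p for p in (el.get("subsequentIds") or "").split(";") if p),
                    assignments=assignments,
                    meta=RecordMeta(created=el.get("created"), agent=el.get("agent")),
                ))
        else:
            warnings.warn(f"foreign element {section.tag!r} ignored",
                          ForeignElementWarning, stacklevel=2)
    return manifest, records


# ---------------------------------------------------------------------------
# Generated XSD + record XML


def _xs(tag: str) -> str:
    return f"{{{XS}}}{tag}"


_RESERVED_RECORD_ELEMENTS: tuple[tuple[str, str, int, int], ...] = (
    # (element, base type, minOccurs, maxOccurs; -1 = unbounded)
    ("unit_id", "xs:string", 1, 1),
    ("unit_id_preceding", "xs:string", 0, -1),
    ("unit_id_origin", "xs:string", 0, 1),
    ("unit_id_subsequent", "xs:string", 0, -1),
    ("unit_domain_elementary", "modcoElementaryDomain", 1, 1),
    ("unit_operation_domain", "modcoOperationDomain", 1, 1),
    ("unit_record_created", "xs:string", 0, 1),
    ("unit_record_agent", "xs:string", 0, 1),
)


def _enum_simple_type(root: etree._Element, name: str, labels: list[str]) -> None:
    st = etree.SubElement(root, _xs("simpleType"), {"name": name})
    restriction = etree.SubElement(st, _xs("restriction"), {"base": "xs:string"})
    for label in labels:
        etree.SubElement(restriction, _xs("enumeration"), {"value": label})


def write_xsd(manifest: SchemaManifest) -> bytes:
    """Generate an XSD for record documents of this manifest.

    Declares a ``Record`` element whose children are the reserved
    identifier/domain elements followed by one optional, repeatable
    element per concept in manifest order.  Categorical concepts map to
    enumerations of their value labels (the ``other value`` fallback
    included when declared), with the free-text supplement carried in a
    ``supplement`` attribute; quantitative concepts to ``xs:decimal`` with
    a ``unitOfMeasure`` attribute; text and sequence concepts to
    ``xs:string``.
    """
    nsmap = {"xs": XS}
    root = etree.Element(_xs("schema"), {"elementFormDefault": "qualified"},
                         nsmap=nsmap)
    _enum_simple_type(root, "modcoElementaryDomain",
                      [d.value for d in ElementaryDomain])
    _enum_simple_type(root, "modcoOperationDomain",
                      [d.value for d in OperationDomain])

    element_names: dict[str, str] = {}
    type_names: dict[str, str] = {}
    for cid, concept in manifest.concepts.items():
        el_name = xml_name(concept.name)
        clash = element_names.get(el_name)
        if clash is not None:
            raise DialectError(
                f"concepts {clash!r} and {cid!r} collide on element name {el_name!r}")
        element_names[el_name] = cid
        if concept.is_categorical:
            tname = f"T_{el_name}"
            _enum_simple_type(root, tname, [v.label for v in concept.values])
            type_names[cid] = tname

    record = etree.SubElement(root, _xs("element"), {"name": "Record"})
    ctype = etree.SubElement(record, _xs("complexType"))
    seq = etree.SubElement(ctype, _xs("sequence"))
    for el_name, base, lo, hi in _RESERVED_RECORD_ELEMENTS:
        etree.SubElement(seq, _xs("element"), {
            "name": el_name, "type": base, "minOccurs": str(lo),
            "maxOccurs": "unbounded" if hi < 0 else str(hi),
        })
    for el_name, cid in element_names.items():
        concept = manifest.concepts[cid]
        holder = etree.SubElement(seq, _xs("element"), {
            "name": el_name, "minOccurs": "0", "maxOccurs": "unbounded"})
        ct = etree.SubElement(holder, _xs("complexType"))
        sc = etree.SubElement(ct, _xs("simpleContent"))
        if concept.is_categorical:
            ext = etree.SubElement(sc, _xs("extension"), {"base": type_names[cid]})
            etree.SubElement(ext, _xs("attribute"),
                             {"name": "supplement", "type": "xs:string"})
        elif concept.data_type is DataTypeToken.QUANTITATIVE:
            ext = etree.SubElement(sc, _xs("extension"), {"base": "xs:decimal"})
            etree.SubElement(ext, _xs("attribute"),
                             {"name": "unitOfMeasure", "type": "xs:string"})
        else:
            etree.SubElement(sc, _xs("extension"), {"base": "xs:string"})
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def write_record_xml(record: UnitRecord, manifest: SchemaManifest) -> bytes:
    """Serialize one unit record as a ``Record`` document for the XSD."""
    root = etree.Element("Record")
    etree.SubElement(root, "unit_id").text = record.unit_id
    for p in sorted(record.preceding_ids):
        etree.SubElement(root, "unit_id_preceding").text = p
    if record.origin_id:
        etree.SubElement(root, "unit_id_origin").text = record.origin_id
    for s in sorted(record.subsequent_ids):
        etree.SubElement(root, "unit_id_subsequent").text = s
    etree.SubElement(root, "unit_domain_elementary").text = record.elementary_domain.value
    etree.SubElement(root, "unit_operation_domain").text = record.operation_domain.value
    if record.meta.created:
        etree.SubElement(root, "unit_record_created").text = record.meta.created
    if record.meta.agent:
        etree.SubElement(root, "unit_record_agent").text = record.meta.agent

    per_concept: dict[str, list[DescriptorAssignment]] = {}
    for a in record.assignments:
        per_concept.setdefault(a.concept_id, []).append(a)
    for cid, concept in manifest.concepts.items():
        for a in per_concept.get(cid, []):
            el = etree.SubElement(root, xml_name(concept.name))
            el.text = a.value
            if a.supplement:
                el.set("supplement", a.supplement)
            if a.unit_of_measure:
                el.set("unitOfMeasure", a.unit_of_measure)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")


def compile_xsd(xsd_doc: bytes) -> etree.XMLSchema:
    """Compile a generated XSD once; reuse the result across validations."""
    return etree.XMLSchema(etree.fromstring(xsd_doc))


def validate_record_xml(record_doc: bytes,
                        xsd: bytes | etree.XMLSchema) -> bool:
    """True iff the record document validates against the generated XSD.

    Pass a precompiled :class:`lxml.etree.XMLSchema` (see
    :func:`compile_xsd`) when validating many records; compilation
    dominates the cost for large schemas.
    """
    schema = xsd if isinstance(xsd, etree.XMLSchema) else compile_xsd(xsd)
    return schema.validate(etree.fromstring(record_doc))


# ---------------------------------------------------------------------------
# RDF / Turtle


def write_rdf(manifest: SchemaManifest) -> bytes:
    """Linked-open-data export: one subject per concept, value, collection.

    Subject URIs are ``namespace_base`` + page slug; value pages are
    qualified by their concept name to keep the per-concept ``other
    value`` states distinct.  The document carries a single ontology
    header subject; the export is deterministic.
    """
    g = Graph()
    g.bind("modco", Namespace(manifest.namespace_base))
    g.bind("mt", MT)
    g.bind("skos", SKOS)
    g.bind("owl", OWL)

    ontology = URIRef(manifest.namespace_base)
    g.add((ontology, RDF.type, OWL.Ontology))
    if manifest.version:
        g.add((ontology, OWL.versionInfo, Literal(manifest.version)))

    collection_refs: dict[str, URIRef] = {}
    for cid in sorted(manifest.collections):
        col = manifest.collections[cid]
        ref = URIRef(manifest.namespace_base + page_slug(col.label) + "_(" + cid + ")")
        collection_refs[cid] = ref
        g.add((ref, RDF.type, SKOS.Collection))
        g.add((ref, RDFS.label, Literal(col.label)))
        if col.parent is not None:
            g.add((ref, SKOS.broader, collection_refs.get(
                col.parent,
                URIRef(manifest.namespace_base
                       + page_slug(manifest.collections[col.parent].label)
                       + "_(" + col.parent + ")"))))

    for cid in sorted(manifest.concepts):
        c = manifest.concepts[cid]
        subject = URIRef(c.uri or manifest.default_uri(c.name))
        g.add((subject, RDF.type, MT.Concept))
        g.add((subject, RDFS.label, Literal(c.name)))
        g.add((subject, MT.dataType, Literal(c.data_type.value)))
        g.add((subject, MT.hierarchyLevel, Literal(c.hierarchy_level,
                                                   datatype=XSD.integer)))
        if c.definition:
            g.add((subject, RDFS.comment, Literal(c.definition)))
        for col_id in sorted(c.collections):
            g.add((collection_refs[col_id], SKOS.member, subject))
        for v in c.values:
            vref = URIRef(v.uri or manifest.default_uri(
                manifest.value_page_name(c, v)))
            g.add((subject, MT.hasValue, vref))
            g.add((vref, RDF.type, MT.ConceptValue))
            g.add((vref, RDFS.label, Literal(v.label)))
            g.add((vref, MT.valueOf, subject))
            if v.is_other_value:
                g.add((vref, MT.isOtherValue, Literal(True)))
    return g.serialize(format="turtle", encoding="utf-8")


def rdf_subject_count(rdf_doc: bytes) -> int:
    """Distinct non-ontology subjects of a Turtle export."""
    g = Graph()
    g.parse(data=rdf_doc, format="turtle")
    subjects = {s for s in g.subjects()}
    headers = {s for s in g.subjects(RDF.type, OWL.Ontology)}
    return len(subjects - headers)


# ---------------------------------------------------------------------------
# EML stub


def write_eml_stub(title: str, creator: str, date: str) -> bytes:
    """Minimal dataset-metadata stub (title / creator / date only)."""
    ns = "https://eml.ecoinformatics.org/eml-2.2.0"
    root = etree.Element(f"{{{ns}}}eml", nsmap={"eml": ns})
    root.set("packageId", page_slug(title))
    root.set("system", "modco")
    dataset = etree.SubElement(root, "dataset")
    etree.SubElement(dataset, "title").text = title
    ind = etree.SubElement(etree.SubElement(dataset, "creator"), "individualName")
    etree.SubElement(ind, "surName").text = creator
    etree.SubElement(dataset, "pubDate").text = date
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
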