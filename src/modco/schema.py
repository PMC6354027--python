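"""In-memory schema model: concepts, vocabularies, collections, statistics.

A schema manifest is the package's single canonical source for a
MOD-CO-style conceptual schema.  It holds:

* **concepts** (descriptors): named attributes of physical or digital
  units, each with a multipartite name, a data type, an optional controlled
  vocabulary of predefined values (descriptor states), a hierarchy level
  and memberships in concept collections;
* **collections**: named, possibly two-level (tree / subtree) groupings of
  concepts.  Collections are non-exclusive — a concept may sit in several,
  or in none.  The one exception is the hierarchy pseudo-collection: the
  five schema hierarchy levels 0–4 partition the concepts, each concept
  belonging to exactly one level;
* **registries**: the closed token sets driving the naming grammar.

The on-disk representation is a single YAML document tagged
``modco-manifest/1`` (documented in the README); :func:`save_manifest`
emits a canonical form that round-trips byte-stably through
:func:`load_manifest`.
"""

from __future__ import annotations

import io
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping
from urllib.parse import quote

import yaml

from .errors import (
    ManifestInvariantError,
    ManifestParseError,
    ManifestReferenceError,
)
from .naming import VocabRegistries, parse_concept_name
from .vocab import DataTypeToken, OTHER_VALUE_LABEL

__all__ = [
    "FORMAT_TAG",
    "ConceptValue",
    "Concept",
    "ConceptCollection",
    "SchemaManifest",
    "SchemaStats",
    "Violation",
    "page_slug",
    "load_manifest",
    "save_manifest",
    "compute_stats",
    "check_consistency",
]

FORMAT_TAG = "modco-manifest/1"

#: Characters kept verbatim in page slugs (MediaWiki-style page naming);
#: spaces become underscores first, everything else is percent-encoded.
_SLUG_SAFE = "_()./:*',-"


def page_slug(page_name: str) -> str:
    """Wiki-style page slug: spaces to underscores, reserved chars percent-encoded."""
    return quote(page_name.replace(" ", "_"), safe=_SLUG_SAFE)


@dataclass(frozen=True)
class ConceptValue:
    """One predefined value (descriptor state) of a categorical concept."""

    value_id: str
    label: str
    is_other_value: bool = False
    uri: str | None = None


@dataclass
class Concept:
    """One schema concept (descriptor)."""

    concept_id: str
    name: str
    data_type: DataTypeToken
    hierarchy_level: int
    values: tuple[ConceptValue, ...] = ()
    collections: tuple[str, ...] = ()
    uri: str = ""
    definition: str | None = None
    cardinality: str | None = None

    @property
    def is_categorical(self) -> bool:
        return self.data_type in (
            DataTypeToken.CATEGORICAL,
            DataTypeToken.CATEGORICAL_PLUS_TEXT,
        )

    def value_by_label(self, label: str) -> ConceptValue | None:
        """Case-insensitive lookup of a predefined value by its label."""
        lowered = label.strip().lower()
        for v in self.values:
            if v.label.lower() == lowered:
                return v
        return None

    @property
    def other_value(self) -> ConceptValue | None:
        for v in self.values:
            if v.is_other_value:
                return v
        return None


@dataclass
class ConceptCollection:
    """A named grouping (tree or subtree) of concepts.

    ``role='hierarchy-level'`` with ``level`` set marks the five
    subcollections of the hierarchy pseudo-collection, whose memberships
    must partition the concepts by level.
    """

    collection_id: str
    label: str
    parent: str | None = None
    role: str | None = None
    level: int | None = None


@dataclass
class SchemaManifest:
    """A complete schema: concepts, collections and naming registries."""

    version: str
    namespace_base: str
    concepts: dict[str, Concept] = field(default_factory=dict)
    collections: dict[str, ConceptCollection] = field(default_factory=dict)
    registries: VocabRegistries = field(default_factory=VocabRegistries)
    #: concept ids whose <string> literal means a sequence payload
    # (derived from data_type; kept for clarity in round-trips)

    def concept_by_name(self, name: str) -> Concept | None:
        for c in self.concepts.values():
            if c.name == name:
                return c
        return None

    def members(self, collection_id: str) -> set[str]:
        """Concept ids belonging to a collection (derived from concepts)."""
        return {
            c.concept_id
            for c in self.concepts.values()
            if collection_id in c.collections
        }

    def collection_depth(self, collection_id: str) -> int:
        """0 for a root tree, 1 for a subtree, deeper values are invalid."""
        depth = 0
        seen = set()
        current = self.collections[collection_id].parent
        while current is not None:
            if current in seen or current not in self.collections:
                break  # cycle or dangling parent; reported by check_consistency
            seen.add(current)
            depth += 1
            current = self.collections[current].parent
        return depth

    def default_uri(self, page_name: str) -> str:
        return self.namespace_base + page_slug(page_name)

    def value_page_name(self, concept: Concept, value: ConceptValue) -> str:
        """Page name of a value, qualified by its concept to stay unique."""
        return f"{concept.name} {value.label}"


@dataclass(frozen=True)
class SchemaStats:
    """Aggregate statistics of a manifest."""

    n_concepts: int
    n_values: int
    n_by_data_type: Mapping[DataTypeToken, int]
    n_by_level: Mapping[int, int]
    n_collections: int
    n_subcollections: int

    @property
    def n_pages(self) -> int:
        """Concept + value pages of the linked-open-data publication."""
        return self.n_concepts + self.n_values


@dataclass(frozen=True)
class Violation:
    """One consistency-rule breach; violations are data, not exceptions."""

    code: str
    entity_id: str
    message: str


def compute_stats(manifest: SchemaManifest) -> SchemaStats:
    """Aggregate counts; deterministic and independent of iteration order."""
    by_type = Counter({t: 0 for t in DataTypeToken})
    by_level = Counter({lvl: 0 for lvl in range(5)})
    n_values = 0
    for c in manifest.concepts.values():
        by_type[c.data_type] += 1
        by_level[c.hierarchy_level] += 1
        n_values += len(c.values)
    roots = sum(1 for col in manifest.collections.values() if col.parent is None)
    subs = len(manifest.collections) - roots
    return SchemaStats(
        n_concepts=len(manifest.concepts),
        n_values=n_values,
        n_by_data_type=dict(by_type),
        n_by_level=dict(by_level),
        n_collections=roots,
        n_subcollections=subs,
    )


def check_consistency(manifest: SchemaManifest) -> list[Violation]:
    """Check every schema invariant; empty list means the manifest is valid.

    Rule codes: ``name-datatype-literal``, ``name-parse``,
    ``duplicate-concept-name``, ``values-on-noncategorical``,
    ``categorical-no-values``, ``duplicate-value-label``,
    ``other-value-multiple``, ``other-value-label``, ``level-range``,
    ``level-partition``, ``collection-depth``, ``dangling-parent``,
    ``dangling-collection-ref``, ``uri-namespace``.
    """
    out: list[Violation] = []
    names_seen: dict[str, str] = {}

    level_collections = {
        cid: col.level
        for cid, col in manifest.collections.items()
        if col.role == "hierarchy-level"
    }

    for cid, col in manifest.collections.items():
        if col.parent is not None and col.parent not in manifest.collections:
            out.append(Violation("dangling-parent", cid,
                                 f"collection {cid!r} has unknown parent {col.parent!r}"))
        elif manifest.collection_depth(cid) > 1:
            out.append(Violation("collection-depth", cid,
                                 f"collection {cid!r} is nested deeper than tree/subtree"))

    for cid, c in manifest.concepts.items():
        literal = c.data_type.literal
        if not c.name.endswith(" " + literal):
            out.append(Violation("name-datatype-literal", cid,
                                 f"name {c.name!r} does not end with {literal!r}"))
        else:
            try:
                parse_concept_name(c.name, manifest.registries,
                                    sequence=c.data_type is DataTypeToken.SEQUENCE)
            except Exception as exc:  # NameParseError
                out.append(Violation("name-parse", cid, str(exc)))
        if c.name in names_seen:
            out.append(Violation("duplicate-concept-name", cid,
                                 f"name {c.name!r} already used by {names_seen[c.name]!r}"))
        else:
            names_seen[c.name] = cid

        if c.is_categorical:
            if not c.values:
                out.append(Violation("categorical-no-values", cid,
                                     "categorical concept has no predefined values"))
        elif c.values:
            out.append(Violation("values-on-noncategorical", cid,
                                 "non-categorical concept carries predefined values"))

        labels = Counter(v.label.lower() for v in c.values)
        for label, n in labels.items():
            if n > 1:
                out.append(Violation("duplicate-value-label", cid,
                                     f"value label {label!r} repeated"))
        others = [v for v in c.values if v.is_other_value]
        if len(others) > 1:
            out.append(Violation("other-value-multiple", cid,
                                 "more than one 'other value' state"))
        for v in others:
            if v.label != OTHER_VALUE_LABEL:
                out.append(Violation("other-value-label", v.value_id,
                                     f"fallback state labelled {v.label!r}"))

        if not 0 <= c.hierarchy_level <= 4:
            out.append(Violation("level-range", cid,
                                 f"hierarchy level {c.hierarchy_level} outside 0..4"))

        memberships = [m for m in c.collections if m in level_collections]
        if len(memberships) > 1 or any(
            level_collections[m] != c.hierarchy_level for m in memberships
        ):
            out.append(Violation("level-partition", cid,
                                 "concept assigned to more than one hierarchy level"))

        for m in c.collections:
            if m not in manifest.collections:
                out.append(Violation("dangling-collection-ref", cid,
                                     f"unknown collection {m!r}"))

        if c.uri and not c.uri.startswith(manifest.namespace_base):
            out.append(Violation("uri-namespace", cid,
                                 f"URI {c.uri!r} outside namespace {manifest.namespace_base!r}"))
        for v in c.values:
            if v.uri and not v.uri.startswith(manifest.namespace_base):
                out.append(Violation("uri-namespace", v.value_id,
                                     f"URI {v.uri!r} outside namespace"))
    return out


# ---------------------------------------------------------------------------
# Serialization


def _manifest_to_dict(manifest: SchemaManifest) -> dict:
    doc: dict = {
        "format": FORMAT_TAG,
        "version": manifest.version,
        "namespace_base": manifest.namespace_base,
        "registries": {
            "operation_domains": list(manifest.registries.operation_domains),
            "properties": list(manifest.registries.properties),
        },
        "collections": [],
        "concepts": [],
    }
    for cid in sorted(manifest.collections):
        col = manifest.collections[cid]
        entry: dict = {"id": col.collection_id, "label": col.label}
        if col.parent is not None:
            entry["parent"] = col.parent
        if col.role is not None:
            entry["role"] = col.role
        if col.level is not None:
            entry["level"] = col.level
        doc["collections"].append(entry)
    for cid in sorted(manifest.concepts):
        c = manifest.concepts[cid]
        entry = {
            "id": c.concept_id,
            "name": c.name,
            "data_type": c.data_type.value,
            "level": c.hierarchy_level,
        }
        if c.collections:
            entry["collections"] = sorted(c.collections)
        if c.uri:
            entry["uri"] = c.uri
        if c.definition is not None:
            entry["definition"] = c.definition
        if c.cardinality is not None:
            entry["cardinality"] = c.cardinality
        if c.values:
            vals = []
            for v in c.values:
                ventry: dict = {"id": v.value_id, "label": v.label}
                if v.is_other_value:
                    ventry["other"] = True
                if v.uri:
                    ventry["uri"] = v.uri
                vals.append(ventry)
            entry["values"] = vals
        doc["concepts"].append(entry)
    return doc


def save_manifest(manifest: SchemaManifest, path: str | os.PathLike | None = None) -> str:
    """Serialize to canonical YAML; returns the document text.

    Canonical means: fixed key order, collections and concepts sorted by
    id, no timestamps — identical manifests serialize byte-identically.
    """
    text = yaml.safe_dump(
        _manifest_to_dict(manifest),
        sort_keys=False,
        allow_unicode=True,
        default_flow_style=False,
        width=1000,
    )
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def _require(entry: Mapping, key: str, where: str):
    if key not in entry:
        raise ManifestParseError(f"missing {key!r} in {where}")
    return entry[key]


def load_manifest(source, *, strict: bool = True) -> SchemaManifest:
    """Load a manifest from a path, file object, YAML text or mapping.

    With ``strict=True`` (default) a manifest breaking any schema
    invariant raises :class:`ManifestInvariantError`; dangling references
    always raise :class:`ManifestReferenceError`.  ``strict=False``
    returns the manifest for inspection with :func:`check_consistency`.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        if hasattr(source, "read"):
            text = source.read()
        elif isinstance(source, (str, os.PathLike)) and (
            isinstance(source, os.PathLike) or "\n" not in str(source) and os.path.exists(source)
        ):
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = str(source)
        try:
            doc = yaml.safe_load(io.StringIO(text))
        except yaml.YAMLError as exc:
            raise ManifestParseError(f"malformed manifest document: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ManifestParseError("manifest document is not a mapping")
    tag = doc.get("format", FORMAT_TAG)
    if tag != FORMAT_TAG:
        raise ManifestParseError(f"unsupported manifest format tag {tag!r}")

    registries_doc = doc.get("registries", {})
    registries = VocabRegistries(
        operation_domains=tuple(registries_doc.get(
            "operation_domains", VocabRegistries().operation_domains)),
        properties=tuple(registries_doc.get("properties", VocabRegistries().properties)),
    )

    manifest = SchemaManifest(
        version=str(doc.get("version", "")),
        namespace_base=str(doc.get("namespace_base", "")),
        registries=registries,
    )

    for entry in doc.get("collections", []) or []:
        cid = str(_require(entry, "id", "collection"))
        if cid in manifest.collections:
            raise ManifestParseError(f"duplicate collection id {cid!r}")
        manifest.collections[cid] = ConceptCollection(
            collection_id=cid,
            label=str(_require(entry, "label", f"collection {cid!r}")),
            parent=entry.get("parent"),
            role=entry.get("role"),
            level=entry.get("level"),
        )

    for entry in doc.get("concepts", []) or []:
        cid = str(_require(entry, "id", "concept"))
        if cid in manifest.concepts:
            raise ManifestParseError(f"duplicate concept id {cid!r}")
        try:
            dtype = DataTypeToken(_require(entry, "data_type", f"concept {cid!r}"))
        except ValueError as exc:
            raise ManifestParseError(f"unknown data type for concept {cid!r}") from exc
        values = []
        seen_vids = set()
        for ventry in entry.get("values", []) or []:
            vid = str(_require(ventry, "id", f"value of concept {cid!r}"))
            if vid in seen_vids:
                raise ManifestParseError(f"duplicate value id {vid!r} in concept {cid!r}")
            seen_vids.add(vid)
            values.append(ConceptValue(
                value_id=vid,
                label=str(_require(ventry, "label", f"value {vid!r}")),
                is_other_value=bool(ventry.get("other", False)),
                uri=ventry.get("uri"),
            ))
        name = str(_require(entry, "name", f"concept {cid!r}"))
        concept = Concept(
            concept_id=cid,
            name=name,
            data_type=dtype,
            hierarchy_level=int(_require(entry, "level", f"concept {cid!r}")),
            values=tuple(values),
            collections=tuple(entry.get("collections", []) or []),
            uri=entry.get("uri") or manifest.namespace_base + page_slug(name),
            definition=entry.get("definition"),
            cardinality=entry.get("cardinality"),
        )
        manifest.concepts[cid] = concept

    # dangling references are hard errors even in non-strict mode
    for cid, col in manifest.collections.items():
        if col.parent is not None and col.parent not in manifest.collections:
            raise ManifestReferenceError(
                f"collection {cid!r} references unknown parent {col.parent!r}")
    for cid, c in manifest.concepts.items():
        for m in c.collections:
            if m not in manifest.collections:
                raise ManifestReferenceError(
                    f"concept {cid!r} references unknown collection {m!r}")

    if strict:
        violations = check_consistency(manifest)
        if violations:
            v = violations[0]
            raise ManifestInvariantError(
                f"{len(violations)} invariant violation(s); first: "
                f"[{v.code}] {v.entity_id}: {v.message}")
    return manifest
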