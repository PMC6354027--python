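# Methods

## The model

MOD-CO models meta-omics laboratory work as a sequence of **workflow
segments** applied to **units**. A unit is either *physical* (field
sample, subsample/aliquot, nucleic-acid extract, amplicon, pool) or
*digital* (measurement data, sequence file, document). Three
**elementary operation domains** classify everything done to a unit:

* **transformation** — invasive change of an object (subsampling,
  extraction, chemical reaction) or of a data representation/format;
* **measurement** — non-invasive analysis yielding values or data,
  including analysis of existing data;
* **transaction** — movement/transfer/deposition of an object or data
  (shipping, storage, archiving, publication).

Each unit is described by one **unit record**: descriptor assignments
drawn from a schema of 653 concepts, plus identifier links
(`preceding`, `origin`, `subsequent`) that concatenate records into a
provenance graph. A workflow segment is one pass of
transformation → measurement → transaction over a physical unit and the
data it generates; segments concatenate into the full workflow from
field sampling to data publication.

Concepts carry one of five data types (text, categorical, quantitative,
sequence, categorical + free text), belong to exactly one of five
hierarchy levels (0 general … 4 object specific — a partition), and to
any number of non-exclusive concept collections (13 trees, 8 of them
subdivided into 24 subtrees). Categorical concepts own a controlled
vocabulary of predefined values; the supplementary **`other value`**
state is the escape hatch that keeps controlled vocabularies mappable
(see below).

## Name grammar

Concept names are multipartite:
`[elementary domain] [operation domain] <core element> [property]
<data-type literal>`. Because core elements are unbounded multiword
phrases and the convention uses no delimiter, segmentation is driven by
closed token registries: the trailing data-type literal is stripped
first (`<category> <string>` greedily before `<string>`), the leading
`unit physical` / `unit digital` / bare `unit` token is matched longest
first, an operation-domain token is consumed if present, and the
*longest registered property suffix* is matched against the remainder's
tail (whole tokens only, and never if the match would empty the core).
The default property registry is deliberately small (`presence`, `name`,
`ID`, `DOI`, `notes`, `URI`, `date/time`, `format`): an over-eager
registry would eat the tails of multiword cores. Parsing and composition
are exact inverses on every fixture name; the property tests additionally
check `parse ∘ compose = id` on generated names whose cores avoid
registry collisions — a name whose core *ends* in a registered property
token is inherently ambiguous under this convention and parses with the
property split off.

`text` and `sequence` both render `<string>`; the literal alone cannot
distinguish them, so the manifest stores the data type explicitly and
the parser takes a `sequence=` hint.

## Validation

Assignment validation is a pure function of the payload, the concept's
data type and (for sequences) a configurable alphabet (default: IUPAC
nucleotide + amino-acid codes, case-insensitive). Three severities:
PASS; WARN for usable-but-flagged data — notably an `other value`
assignment lacking its free-text supplement, since the fallback state is
meant to carry the original wording of the source value; FAIL for type
mismatches, out-of-vocabulary categorical values, alphabet violations,
self-loops. Failures are report entries with machine-readable reason
codes, never exceptions; only broken references (a concept id absent
from the manifest) raise. Dates/times are stored as strings and not
forced into ISO-8601: the schema itself carries separate format
concepts, so hard-coding a format here would be wrong. Multi-valued
categorical assignments are allowed (cardinalities are not constrained
by the schema; the manifest reserves an optional, unconstrained
`cardinality` field).

## Workflow segmentation

The provenance graph takes an edge per `preceding` link (parent →
record) and per `subsequent` link (record → child); reciprocal
declarations merge. Cycles and dangling ids are hard errors — provenance
must be a DAG. Pooling (e.g. amplicons combined into one sequencing
pool) is an ordinary node with in-degree > 1.

The segment boundary rule is this package's operationalization of a
model described in prose, so it is stated explicitly:

> A physical record with operation domain *transformation* and a
> physical parent **opens a new segment** (it is the subsample/aliquot
> starting the next pass). Sibling aliquots opening from parents in the
> same segment share the new segment; a pooling node (in-degree > 1)
> **continues** its parents' segment. All other records — digital
> records, physical measurements and transactions — join their parent's
> segment, i.e. transitively the segment of their nearest physical
> ancestor. A node with parents in several segments joins the
> most downstream one.

The rationale: each segment "usually starts with subsampling or
aliquotation (i.e. transformation) of a physical unit", parallel
aliquots of one step belong to one segment, and pooling is the
convergence of a step, not the start of a new one. Under this rule the
use-case workflow (sampling → extraction → amplification/pooling → HTS
sequencing) partitions into exactly 4 segments; the fourth begins with
the pooled library being loaded for sequencing (a physical
transformation), to which the digital read-data unit and its archival
attach. Segments always partition the node set (property-tested on
random record sets). Processing order is a lexicographic topological
sort, making the partition deterministic.

`derive_origins` computes each node's root ancestors and flags
disagreement with the declared `unit_id_origin`; a declared origin that
is not among the derived roots is reported, not repaired.

## Serialization

* **Manifest YAML** (`modco-manifest/1`): the canonical source.
  `save_manifest` sorts collections/concepts by id and fixes key order,
  so canonical documents round-trip byte-stably.
* **SDD-style XML** (`modco-sdd/1`): a minimal dialect in the spirit of
  the TDWG Structure of Descriptive Data family — `Descriptor` elements
  with `States`, `Description` elements for records — *not* a certified
  SDD 1.1 implementation (the full standard's element inventory is far
  larger than needed here). Foreign elements are skipped with a warning;
  a `StateRef` to an undeclared descriptor or state is a dialect error
  carrying the element path. Canonical output is a serialization fixed
  point.
* **XSD**: one element per concept under a `Record` element, in manifest
  order; categorical concepts become enumerations of their value labels
  with the free-text supplement carried in a `supplement` attribute on
  the same element (an attribute rather than a paired element keeps the
  enumeration a simple content type); quantitative maps to `xs:decimal`
  with a `unitOfMeasure` attribute; text and sequence to `xs:string`.
  Element names use a documented slug rule (spaces and non-NCName
  characters → `_`); collisions are hard errors. For enumeration and
  decimal payloads, XSD validation and `validate_record` agree by
  construction (cross-checked on 100 synthetic records); the XSD cannot
  see sequence-alphabet or record-level (self-loop) failures, which is
  why the validator, not the XSD, is authoritative.
* **RDF/Turtle**: one subject per concept, value and collection under
  `namespace_base` + wiki-style page slug (spaces → underscores,
  reserved characters percent-encoded). Value page names are qualified
  by their concept's name because value labels repeat across concepts
  (every categorical concept may carry `other value`). Predicates come
  from a fixed package vocabulary plus SKOS (`skos:member`,
  `skos:broader`); one ontology-header subject carries the version.
  Graph construction is sorted, so serialization is deterministic.
* **EML**: a deliberate stub (title/creator/date) — dataset-level
  project metadata is out of scope.

## Mapping

Concept correspondences carry a SKOS mapping type. Only `exact` and
`close` matches substitute categorical values by default; `broad` /
`narrow` / `related` are transported as metadata and substitute only
under an explicit opt-in, since an inexact correspondence between value
lists is a curatorial judgement, not a mechanical rewrite. Values
without a correspondence follow the chosen fallback policy
(`other_value` → target fallback state + original wording as
supplement; `whole_text` → original wording as the payload; `drop`).
Non-categorical payloads transfer as a whole. Two invariants hold for
every record and policy: *conservation* (mapped + fallback + dropped =
total assignments) and *no invention* (every categorical value written
exists in the target vocabulary — violations raise). An `other_value`
fallback against a target concept lacking the fallback state degrades
to a reported drop.

## The packaged fixture and the synthetic generators

The full 653-concept inventory lives on the schema's wiki and is not
redistributed; the packaged fixture (`modco.fixture`, built
deterministically at import seed 20180328) is therefore
**statistics-complete but content-exemplary**. Exact reproductions:
concept totals per data type (398/238/7/10), per hierarchy level
(61/277/49/215/51), 1810 values, and every published per-(sub)collection
membership count — including the deliberately non-partitioning ones
(Digital 235 + Physical 380 = 615 ≠ 653; Transformation 241 +
Measurement 174 + Transaction 112 = 527 ≠ 653; the remainder are bare
`unit` record-management concepts). Name-segment marginals are chosen to
make those collection counts *structural*: the Physical subcollection
contains exactly the concepts whose names carry `unit physical`, the
Identifiers subtrees exactly the concepts with the corresponding
property token. The dozen concepts whose names and value lists are part
of the published schema documentation appear verbatim (the level-0
identifier and record-management descriptors, the domain descriptors
with their 2 and 3 states, the device-URI, index-primer, muscle-tissue
and protocol-modification descriptors); all other concepts are
grammar-conformant numbered placeholders, and value lists beyond the
exemplars are evenly distributed synthetic states (7–8 per categorical
concept including `other value`). The
`categorical + free text` type is realized 0 times in the fixture so
the four published data-type counts stay exact; it is exercised by the
unit and property tests.

What passing tests on this fixture do and do not show: they verify the
engine — counting, parsing, validation, graph logic, serialization —
against the schema's published structure, but say nothing about the
semantic content of the real inventory (definitions, real value lists,
real collection assignments), which the manifest format can hold but
the repository does not ship.

The GBOL-2-style workflow generator emulates the published use case —
four segments from leaf sampling of rosaceous fruit trees to MiSeq
read-data generation — as 10 unit records with realistic structure:
a pooling node of in-degree 2, one derived origin, domain-appropriate
assignments (ITS primer names, a fluorometric concentration with unit,
a 20–60 nt read payload drawn from the nucleotide alphabet). It does
not simulate sequence content, chimeras or laboratory error models.
Payload randomness is pure in the seed; structure (ids, links, segment
shape) is seed-independent by design, since it *is* the use case.

## Numerical and procedural choices

* Quantitative payloads are validated with float parsing; the XSD maps
  them to `xs:decimal` (exponent-free literals are used throughout the
  generators, where the two notions coincide).
* Case-insensitive matching for value labels (labels must be unique
  case-insensitively within a concept); exact matching everywhere else.
* Problem sizes: property tests run 50 derandomized examples per
  invariant; cross-validation checks use 100 synthetic records against
  a 15-concept schema (XSD compilation for the full 653-concept schema
  costs seconds and adds nothing to the check); generator/validator
  agreement runs 50 seeds. The whole suite completes in a few seconds.

## Known limitations

* The authoritative XSD and SDD publications of the schema are not
  reproduced; this package's dialects are self-consistent, documented,
  and make no claim of byte compatibility with them.
* One operation domain per record: a record that joins several workflow
  segments (the schema's level-3 redundancies allow this) must be
  represented as several linked records.
* `subsequent` links must resolve within the data set; cross-dataset
  references are not supported.
* Mapping of quantitative modifiers via SKOS properties is not
  implemented (announced for a future schema version, not specified).
* Semantic-MediaWiki site generation, the DWB-DD SQL implementation and
  full EML export are out of scope.
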