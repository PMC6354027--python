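# modco

An executable data model for **MOD-CO** (Meta-omics Data and Collection
Objects), the conceptual schema for processing sample data in meta-omics
research. MOD-CO describes the *whole* operational workflow — from an
environmental sample gathered in the field, through nucleic-acid
extraction, amplification and pooling, to HTS data generation and
archival — as **unit records** (one per physical or digital unit) built
from **concepts** (descriptors) with controlled vocabularies, linked by
unit identifiers into provenance chains. It is the data-model backbone a
LIMS or electronic lab notebook needs for meta-omics work, where
schemas focused on downstream data exchange (Darwin Core, ABCD, MIxS,
GGBN) do not cover the upstream laboratory reality.

This package turns the schema into running code:

* **`modco.schema`** — the schema engine: manifests of concepts,
  predefined values (descriptor states), concept collections and
  hierarchy levels, with consistency checking and aggregate statistics.
* **`modco.naming`** — the multipartite concept-name grammar:
  `[elementary domain] [operation domain] <core element> [property]
  <data-type literal>`, with a deterministic, registry-driven parser and
  exact round-trip composition.
* **`modco.records`** — unit records with descriptor assignments,
  three-severity validation (PASS / WARN / FAIL with machine-readable
  reason codes) and a CSV record-table round-trip.
* **`modco.workflow`** — directed acyclic provenance graphs over
  concatenated records (pooling = in-degree > 1), derived origins, and
  partition into workflow segments
  (transformation → measurement → transaction).
* **`modco.io_formats`** — deterministic serializers: a documented
  SDD-style XML dialect, a generated XSD that record documents validate
  against, and an RDF/Turtle linked-open-data export with one stable URI
  per concept, value and collection.
* **`modco.mapping`** — SKOS-typed cross-schema mapping
  (exact/close/broad/narrow/related match) with the categorical fallback
  rules: `other_value` (target fallback state + original wording as
  supplement), `whole_text`, or `drop`.
* **`modco.synthetic` / `modco.fixture`** — deterministic generators,
  including the packaged *statistics-complete* fixture reproducing every
  published aggregate of schema version 1.0 (653 concepts, 1810
  predefined values, 2463 concept+value pages, 5 hierarchy levels,
  13 collections + 24 subcollections) and a four-segment fungal
  microbiome barcoding workflow (the GBOL 2 use case).
* **`modco.cli`** — the `modco` command-line tool over all of the above.

## Worked example

The packaged fixture (special schema path `fixture`) reproduces the
published aggregate statistics of MOD-CO 1.0:

```sh
$ modco schema stats fixture
{
  "n_concepts": 653,
  "n_values": 1810,
  "n_pages": 2463,
  "n_by_data_type": {
    "text": 398, "categorical": 238, "quantitative": 7,
    "sequence": 10, "categorical_text": 0
  },
  "n_by_level": {"0": 61, "1": 277, "2": 49, "3": 215, "4": 51},
  "n_collections": 13,
  "n_subcollections": 24
}
```

653 concepts partition over the five hierarchy levels (61 + 277 + 49 +
215 + 51) and, independently, over the data types (398 + 238 + 7 + 10);
653 concepts + 1810 values give the 2463 linked pages of the LOD
publication; 13 collection trees carry 24 subtrees (37 groupings in
total).

Concept names decompose deterministically:

```sh
$ modco name parse "unit digital measurement device URI <string>"
{
  "elementary_domain": "digital",
  "operation_domain": "measurement",
  "core_element": "device",
  "property": "URI",
  "data_type": "text"
}
```

The generated barcoding use case — leaf sampling → total nucleic-acid
extraction → marker-gene amplification with amplicon pooling → MiSeq
read-data generation — validates cleanly and partitions into exactly the
four expected workflow segments, with the amplicon pool as the
in-degree-2 node and the field sample as the single derived origin:

```sh
$ modco synth gbol2 --seed 1 --out gbol2.csv
$ modco validate gbol2.csv --schema fixture
10 records, 0 failures
$ modco workflow segments gbol2.csv --schema fixture
segment 1: [transaction,transformation] GBOL2-SAMPLE-001 GBOL2-SAMPLE-DEP-001
segment 2: [measurement,transformation] GBOL2-EXTRACT-001 GBOL2-EXTRACT-QC-001
segment 3: [transformation] GBOL2-AMPLICON-001 GBOL2-AMPLICON-002 GBOL2-POOL-001
segment 4: [measurement,transaction,transformation] GBOL2-LIB-001 GBOL2-READS-001 GBOL2-READS-ARCH-001
```

Exports (`modco export sdd|xsd|rdf --schema fixture --out FILE`) are
byte-deterministic; `modco map` rewrites record tables between schemas
under a CSV crosswalk.

## Manifest format

A schema manifest is one YAML document tagged `modco-manifest/1`:

```yaml
format: modco-manifest/1
version: '1.0'
namespace_base: 'http://www.mod-co.net/wiki/modco:'
registries:
  operation_domains: [transformation, measurement, transaction]
  properties: [presence, name, ID, DOI, notes, URI, date/time, format]
collections:
- id: traits
  label: Object traits
- id: traits-tissue
  label: Tissue
  parent: traits            # at most trees and subtrees (depth <= 1)
concepts:
- id: c1
  name: unit physical (host) organism muscle tissue <category>
  data_type: categorical    # text|categorical|quantitative|sequence|categorical_text
  level: 4                  # hierarchy level 0..4, exactly one per concept
  collections: [traits, traits-tissue]
  uri: 'http://www.mod-co.net/wiki/modco:unit_physical_(host)_organism_muscle_tissue_%3Ccategory%3E'
  values:
  - {id: v1, label: cardiac}
  - {id: v2, label: skeletal}
  - {id: v3, label: smooth muscle}
  - {id: v4, label: other value, other: true}   # supplementary fallback state
```

Concept URIs default to `namespace_base` + wiki-style page slug (spaces
→ underscores, reserved characters percent-encoded). `text` and
`sequence` concepts both render the `<string>` literal; the manifest's
explicit `data_type` disambiguates them. `save_manifest` emits a
canonical form that round-trips byte-stably through `load_manifest`.

Record tables are CSV with reserved columns `unit_id`,
`unit_id_preceding` (semicolon-joined), `unit_id_origin`,
`unit_id_subsequent`, `unit_domain_elementary`, `unit_operation_domain`,
`unit_record_created`, `unit_record_agent`, and one column per assigned
concept headed by its full name (` #N` suffix for repeated columns).
Categorical cells are `label` or `label | supplement`; quantitative
cells `number` or `number unit`.

See `docs/methods.md` for the model, the segment-boundary rule, the
fixture's construction and known limitations.

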