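"""Schema model: loading, statistics, consistency checking, round-trip."""

from __future__ import annotations

import pytest

from modco.errors import (
    ManifestInvariantError,
    ManifestParseError,
    ManifestReferenceError,
)
from modco.schema import (
    Concept,
    ConceptCollection,
    ConceptValue,
    SchemaManifest,
    check_consistency,
    compute_stats,
    load_manifest,
    page_slug,
    save_manifest,
)
from modco.vocab import DataTypeToken

from conftest import NS, make_value, small_manifest


def codes(manifest):
    return {v.code for v in check_consistency(manifest)}


def test_empty_manifest_document():
    m = load_manifest("format: modco-manifest/1\nversion: '0.0'\n"
                      "namespace_base: 'urn:x:'\n")
    stats = compute_stats(m)
    assert stats.n_concepts == 0
    assert stats.n_values == 0
    assert stats.n_pages == 0
    assert sum(stats.n_by_level.values()) == 0


def test_yaml_roundtrip_is_byte_stable(tmp_path):
    m = small_manifest()
    text1 = save_manifest(m, tmp_path / "m.yaml")
    m2 = load_manifest(tmp_path / "m.yaml")
    text2 = save_manifest(m2)
    assert text1 == text2
    assert save_manifest(load_manifest(text2)) == text2


def test_stats_pages_and_partitions():
    m = SchemaManifest(version="1.0", namespace_base=NS)
    m.concepts["c1"] = Concept(
        "c1", "unit physical (host) organism muscle tissue <category>",
        DataTypeToken.CATEGORICAL, 4,
        values=(make_value(1, "cardiac"), make_value(2, "skeletal"),
                make_value(3, "smooth muscle"), make_value(4, "other value", True)),
        uri=NS + "x")
    stats = compute_stats(m)
    assert stats.n_pages == 5  # one concept plus its four states
    assert sum(stats.n_by_level.values()) == stats.n_concepts
    assert sum(stats.n_by_data_type.values()) == stats.n_concepts


def test_stats_order_independent():
    m = small_manifest()
    permuted = SchemaManifest(version=m.version, namespace_base=m.namespace_base,
                              collections=m.collections)
    for cid in reversed(list(m.concepts)):
        permuted.concepts[cid] = m.concepts[cid]
    assert compute_stats(permuted) == compute_stats(m)
    assert compute_stats(m) == compute_stats(m)  # idempotent


def test_small_manifest_is_consistent():
    assert check_consistency(small_manifest()) == []


def test_collection_membership_need_not_partition():
    """Membership sums differing from the concept total (the published
    domain collections sum to 615 and 527 out of 653) are legal."""
    m = small_manifest()
    total_membership = sum(len(m.members(cid)) for cid in m.collections)
    assert total_membership != len(m.concepts)
    assert check_consistency(m) == []


def test_level_partition_violation():
    """A concept claimed by two hierarchy-level subcollections is flagged."""
    m = small_manifest()
    m.collections["lvl-3"] = ConceptCollection(
        "lvl-3", "level 3", parent="traits", role="hierarchy-level", level=3)
    m.collections["lvl-4"] = ConceptCollection(
        "lvl-4", "level 4", parent="traits", role="hierarchy-level", level=4)
    c = m.concepts["c1"]  # hierarchy_level 4
    c.collections = c.collections + ("lvl-3", "lvl-4")
    assert "level-partition" in codes(m)


def test_collection_depth_violation():
    m = small_manifest()
    m.collections["deep"] = ConceptCollection("deep", "too deep",
                                              parent="traits-tissue")
    assert "collection-depth" in codes(m)


def test_categorical_without_values_violation():
    m = small_manifest()
    m.concepts["c9"] = Concept("c9", "unit physical bare list <category>",
                               DataTypeToken.CATEGORICAL, 2, uri=NS + "y")
    assert "categorical-no-values" in codes(m)


def test_values_on_noncategorical_violation():
    m = small_manifest()
    m.concepts["c2"].values = (make_value(1, "stray"),)
    assert "values-on-noncategorical" in codes(m)


def test_duplicate_value_label_case_insensitive():
    m = small_manifest()
    c = m.concepts["c1"]
    c.values = c.values + (ConceptValue("v9", "CARDIAC"),)
    assert "duplicate-value-label" in codes(m)


def test_other_value_label_fixed():
    m = small_manifest()
    c = m.concepts["c1"]
    c.values = tuple(
        ConceptValue(v.value_id, "misc", True) if v.is_other_value else v
        for v in c.values)
    assert "other-value-label" in codes(m)


def test_uri_outside_namespace_violation():
    m = small_manifest()
    m.concepts["c2"].uri = "http://elsewhere.example/x"
    assert "uri-namespace" in codes(m)


def test_name_literal_mismatch_violation():
    m = small_manifest()
    m.concepts["c2"].data_type = DataTypeToken.QUANTITATIVE
    assert "name-datatype-literal" in codes(m)


def test_dangling_collection_reference_raises():
    text = save_manifest(small_manifest())
    broken = text.replace("- traits\n", "- missing-collection\n")
    with pytest.raises(ManifestReferenceError, match="missing-collection"):
        load_manifest(broken)


def test_dangling_parent_raises():
    m = small_manifest()
    m.collections["orphan"] = ConceptCollection("orphan", "Orphan", parent="nope")
    with pytest.raises(ManifestReferenceError, match="nope"):
        load_manifest(save_manifest(m))


def test_strict_load_rejects_invariant_breach():
    m = small_manifest()
    m.concepts["c9"] = Concept("c9", "unit physical bare list <category>",
                               DataTypeToken.CATEGORICAL, 2, uri=NS + "y")
    text = save_manifest(m)
    with pytest.raises(ManifestInvariantError, match="categorical-no-values"):
        load_manifest(text)
    relaxed = load_manifest(text, strict=False)
    assert "c9" in relaxed.concepts


@pytest.mark.parametrize("text", [
    "format: something-else/9\n",
    "concepts: [{name: incomplete}]\n",
    "- just\n- a list\n",
])
def test_malformed_documents_raise_parse_error(text):
    with pytest.raises(ManifestParseError):
        load_manifest(text)


def test_page_slug_rule():
    assert page_slug("unit digital measurement device URI <string>") == (
        "unit_digital_measurement_device_URI_%3Cstring%3E")
    assert page_slug("level 0 (general)") == "level_0_(general)"
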