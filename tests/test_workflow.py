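"""Provenance-graph construction, origin derivation, segment partition."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, strategies as st

from modco.errors import GraphCycleError, GraphReferenceError, RecordFormatError
from modco.records import UnitRecord
from modco.workflow import (
    build_graph,
    derive_origins,
    segment_partition,
    to_dot,
    to_node_link,
)
from modco.vocab import ElementaryDomain, OperationDomain

P, D = ElementaryDomain.PHYSICAL, ElementaryDomain.DIGITAL
T, M, X = (OperationDomain.TRANSFORMATION, OperationDomain.MEASUREMENT,
           OperationDomain.TRANSACTION)


def rec(uid, elem=P, op=T, preceding=(), subsequent=(), origin=None):
    return UnitRecord(unit_id=uid, elementary_domain=elem, operation_domain=op,
                      preceding_ids=frozenset(preceding),
                      subsequent_ids=frozenset(subsequent), origin_id=origin)


def chain(ids, **kw):
    return [rec(uid, preceding=ids[i - 1:i], **kw) for i, uid in enumerate(ids)]


def test_chain_graph_shape():
    wg = build_graph(chain(["A", "B", "C", "D"]))
    assert wg.n_nodes == 4
    assert wg.n_edges == 3
    assert wg.origins == {"A"}


def test_pooling_node_in_degree():
    records = [
        rec("B"), rec("C"),
        rec("B2", preceding=["B"], subsequent=["P"]),
        rec("C2", preceding=["C"], subsequent=["P"]),
        rec("P", preceding=["B2", "C2"]),
    ]
    wg = build_graph(records)
    assert wg.graph.in_degree("P") == 2
    # reciprocal preceding/subsequent declarations merge into single edges
    assert wg.n_edges == 4


def test_self_reference_is_cycle_error():
    with pytest.raises(GraphCycleError):
        build_graph([rec("A", preceding=["A"])])


def test_cycle_error_lists_offending_cycle():
    records = [rec("A", preceding=["B"]), rec("B", preceding=["A"])]
    with pytest.raises(GraphCycleError) as err:
        build_graph(records)
    assert set(err.value.cycle) == {"A", "B"}


def test_dangling_reference_rejected():
    with pytest.raises(GraphReferenceError, match="ghost"):
        build_graph([rec("A", preceding=["ghost"])])


def test_duplicate_unit_ids_rejected():
    with pytest.raises(RecordFormatError):
        build_graph([rec("A"), rec("A")])


def test_record_order_invariance():
    records = chain(["A", "B", "C", "D"])
    shuffled = list(records)
    random.Random(3).shuffle(shuffled)
    a, b = build_graph(records), build_graph(shuffled)
    assert set(a.graph.edges) == set(b.graph.edges)
    assert a.origins == b.origins
    assert to_node_link(a) == to_node_link(b)


def test_derived_origins_on_chain():
    wg = build_graph(chain(["A", "B", "C", "D"], origin="A"))
    origins = derive_origins(wg)
    assert all(origins[n]["derived"] == {"A"} for n in "ABCD")
    assert all(origins[n]["agrees"] for n in "ABCD")


def test_pooled_node_has_both_roots():
    records = [
        rec("A1"), rec("A2"),
        rec("B1", preceding=["A1"]), rec("B2", preceding=["A2"]),
        rec("P", preceding=["B1", "B2"]),
    ]
    origins = derive_origins(build_graph(records))
    assert origins["P"]["derived"] == {"A1", "A2"}


def test_declared_origin_mismatch_flagged():
    records = chain(["A", "B"], origin=None)
    records[1] = rec("B", preceding=["A"], origin="Z")
    records.append(rec("Z"))
    origins = derive_origins(build_graph(records))
    assert origins["B"]["agrees"] is False


def test_single_record_single_segment():
    segments = segment_partition(build_graph([rec("A")]))
    assert len(segments) == 1
    assert segments[0].member_ids == ("A",)


def test_digital_child_joins_parent_segment():
    """A digital measurement hanging off segment 2's physical product
    belongs to segment 2, not a segment of its own."""
    records = [
        rec("S1"),                                   # segment 1 (root sample)
        rec("S2", preceding=["S1"]),                 # physical aliquot: segment 2
        rec("QC", elem=D, op=M, preceding=["S2"]),   # digital child
    ]
    segments = segment_partition(build_graph(records))
    assert len(segments) == 2
    assert set(segments[1].member_ids) == {"S2", "QC"}
    assert segments[1].operations_present == {T, M}


def test_parallel_aliquots_share_a_segment():
    records = [
        rec("S"),
        rec("A1", preceding=["S"]),
        rec("A2", preceding=["S"]),
        rec("P", preceding=["A1", "A2"]),   # pooling continues the segment
    ]
    segments = segment_partition(build_graph(records))
    assert len(segments) == 2
    assert set(segments[1].member_ids) == {"A1", "A2", "P"}


def test_gbol2_partition(fixture_schema, gbol2_records):
    wg = build_graph(gbol2_records)
    segments = segment_partition(wg)
    assert len(segments) == 4
    assert wg.graph.in_degree("GBOL2-POOL-001") >= 2
    union = [uid for seg in segments for uid in seg.member_ids]
    assert sorted(union) == sorted(wg.records)          # partition covers
    assert len(union) == len(set(union))                # ... disjointly


@given(st.integers(min_value=1, max_value=12), st.integers(min_value=0, max_value=10))
def test_chain_edge_count_invariant(n, seed):
    """On pool-free unions of chains, |edges| = |nodes| - |origins|."""
    rng = random.Random(seed)
    records = []
    for c in range(1 + seed % 3):
        ids = [f"u{c}-{i}" for i in range(n)]
        ops = [rng.choice([T, M, X]) for _ in ids]
        records += [
            rec(uid, op=ops[i], preceding=ids[i - 1:i]) for i, uid in enumerate(ids)
        ]
    wg = build_graph(records)
    assert wg.n_edges == wg.n_nodes - len(wg.origins)
    members = [uid for seg in segment_partition(wg) for uid in seg.member_ids]
    assert sorted(members) == sorted(wg.records)


def test_dot_export_mentions_every_node():
    wg = build_graph(chain(["A", "B"]))
    dot = to_dot(wg)
    assert '"A" -> "B";' in dot
    assert dot.startswith("digraph")
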