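"""Provenance graphs over concatenated unit records and workflow segments.

Unit records concatenate into a workflow through their identifier links:
every ``preceding_id`` contributes a parent→child edge, every
``subsequent_id`` a child edge from the declaring record.  The result must
be a directed acyclic graph; *pooling* — a unit derived from several
parents, e.g. an amplicon pool — is an ordinary node with in-degree > 1.

A *workflow segment* is one pass of the elementary operations
(transformation, measurement, transaction) applied to a physical unit and
the data it generates.  Segments are recovered from the graph with one
boundary rule, stated here because it drives everything downstream:

    A physical unit record whose operation domain is *transformation* and
    that descends from a physical parent **opens a new segment** — it is
    the subsample/aliquot starting the next pass.  Two refinements:
    sibling aliquots opening from parents in the same segment share the
    new segment (parallel aliquots of one step are one segment), and a
    pooling node (in-degree > 1) **continues** its parents' segment —
    pooling is the convergence of a step, not the start of a new one.
    Every other record (digital records, physical measurements and
    transactions) joins the segment of its parent, which transitively is
    the segment of its nearest physical ancestor.

Segments partition the node set; each reports which of the three
elementary operations occur in it.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import GraphCycleError, GraphReferenceError, RecordFormatError
from .records import UnitRecord
from .vocab import ElementaryDomain, OperationDomain

__all__ = [
    "WorkflowGraph",
    "WorkflowSegment",
    "build_graph",
    "derive_origins",
    "segment_partition",
    "to_node_link",
    "to_dot",
]


@dataclass
class WorkflowGraph:
    """A validated provenance DAG over unit records."""

    records: dict[str, UnitRecord]
    graph: nx.DiGraph
    origins: frozenset[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class WorkflowSegment:
    """One maximal segment of the workflow."""

    index: int
    member_ids: tuple[str, ...]
    operations_present: frozenset[OperationDomain]


def build_graph(records: list[UnitRecord]) -> WorkflowGraph:
    """Assemble the provenance graph from identifier links.

    Edges from ``preceding_ids`` (parent → record) and ``subsequent_ids``
    (record → child) are merged; reciprocal declarations deduplicate
    silently.  Duplicate unit ids, dangling ids and cycles are hard
    errors.  The result is independent of record order.
    """
    by_id: dict[str, UnitRecord] = {}
    for r in records:
        if r.unit_id in by_id:
            raise RecordFormatError(f"duplicate unit_id {r.unit_id!r}")
        by_id[r.unit_id] = r

    g = nx.DiGraph()
    g.add_nodes_from(sorted(by_id))
    for r in records:
        for ref in sorted(r.preceding_ids | r.subsequent_ids):
            if ref not in by_id:
                raise GraphReferenceError(
                    f"record {r.unit_id!r} links to unknown unit {ref!r}")
        for p in sorted(r.preceding_ids):
            g.add_edge(p, r.unit_id)
        for s in sorted(r.subsequent_ids):
            g.add_edge(r.unit_id, s)

    if not nx.is_directed_acyclic_graph(g):
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise GraphCycleError(cycle)

    origins = frozenset(n for n in g.nodes if g.in_degree(n) == 0)
    return WorkflowGraph(records=by_id, graph=g, origins=origins)


def derive_origins(wg: WorkflowGraph) -> dict[str, dict]:
    """Root ancestors of every unit, checked against declared origins.

    For each unit id returns ``{"derived": set of root unit ids,
    "declared": declared origin_id or None, "agrees": bool}``; a root's
    derived set is itself.  ``agrees`` is True when no origin is declared
    or the declared origin is among the derived roots.
    """
    out: dict[str, dict] = {}
    for node in sorted(wg.graph.nodes):
        ancestors = nx.ancestors(wg.graph, node)
        roots = {a for a in ancestors if a in wg.origins}
        if node in wg.origins:
            roots = {node}
        declared = wg.records[node].origin_id
        out[node] = {
            "derived": roots,
            "declared": declared,
            "agrees": declared is None or declared in roots,
        }
    return out


def _opens_segment(wg: WorkflowGraph, node: str) -> bool:
    r = wg.records[node]
    if r.elementary_domain is not ElementaryDomain.PHYSICAL:
        return False
    if r.operation_domain is not OperationDomain.TRANSFORMATION:
        return False
    if wg.graph.in_degree(node) != 1:
        return False  # roots open implicitly; pooling continues its segment
    parent = next(iter(wg.graph.predecessors(node)))
    return wg.records[parent].elementary_domain is ElementaryDomain.PHYSICAL


def segment_partition(wg: WorkflowGraph) -> list[WorkflowSegment]:
    """Partition the graph into workflow segments (boundary rule above).

    Deterministic: nodes are processed in topological order with
    lexicographic tie-breaking; a node with parents in several segments
    joins the most downstream (highest-index) one.
    """
    order = list(nx.lexicographical_topological_sort(wg.graph))
    seg_of: dict[str, int] = {}
    members: dict[int, list[str]] = {}
    opened_from: dict[int, int] = {}  # parent segment -> segment its aliquots opened
    next_seg = 0

    for node in order:
        parents = list(wg.graph.predecessors(node))
        if not parents:
            seg = next_seg
            next_seg += 1
        elif _opens_segment(wg, node):
            parent_seg = seg_of[parents[0]]
            if parent_seg in opened_from:
                seg = opened_from[parent_seg]
            else:
                seg = next_seg
                next_seg += 1
                opened_from[parent_seg] = seg
        else:
            seg = max(seg_of[p] for p in parents)
        seg_of[node] = seg
        members.setdefault(seg, []).append(node)

    segments = []
    for index in sorted(members):
        ids = tuple(members[index])
        ops = frozenset(wg.records[n].operation_domain for n in ids)
        segments.append(WorkflowSegment(index=index, member_ids=ids,
                                        operations_present=ops))
    return segments


def to_node_link(wg: WorkflowGraph) -> dict:
    """JSON-ready node-link representation (stable ordering)."""
    return {
        "directed": True,
        "nodes": [
            {
                "id": n,
                "elementary_domain": wg.records[n].elementary_domain.value,
                "operation_domain": wg.records[n].operation_domain.value,
            }
            for n in sorted(wg.graph.nodes)
        ],
        "links": [{"source": u, "target": v} for u, v in sorted(wg.graph.edges)],
        "origins": sorted(wg.origins),
    }


def to_dot(wg: WorkflowGraph) -> str:
    """Graphviz DOT export for quick visual inspection."""
    lines = ["digraph workflow {", "  rankdir=LR;"]
    for n in sorted(wg.graph.nodes):
        r = wg.records[n]
        shape = "box" if r.elementary_domain is ElementaryDomain.PHYSICAL else "ellipse"
        lines.append(f'  "{n}" [shape={shape} label="{n}\\n{r.operation_domain.value}"];')
    for u, v in sorted(wg.graph.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
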