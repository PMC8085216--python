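"""Breakpoint multigraph: segments, head/tail nodes, and segment /
reference / SV edges with integer multiplicities.

The i-th genomic segment is represented by a pair of nodes — its head (5'
end) and tail (3' end). A *segment edge* joins the head and tail of the same
segment and its multiplicity is the segment's copy number. A *reference
edge* joins tail(i) to head(i+1) of reference-adjacent segments. An *SV
edge* is a novel adjacency. After multiplicity solving, every non-telomeric
node s satisfies the copy-number balance condition

    mu(e_s(s)) = mu(e_r(s)) + sum_{v in E_v(s)} mu(v)

which guarantees an Eulerian decomposition into linear and circular
chromosomes. Self-loop SV edges (fold-back adjacencies whose two breakends
land on the same node) count twice in the SV sum, once per endpoint stub.

Coordinates are 1-based inclusive. Zero-length *virtual segments*
(end = start - 1) exist only where exactly reciprocal SV breakpoints would
otherwise be pruned by the balance program's difference cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

from .svcalls import HEAD, TAIL, SVCall, _chrom_key

SEGMENT = "segment"
REFERENCE = "reference"
SV = "sv"


class Node(NamedTuple):
    seg: int
    side: str
    hap: int = 0  # 0 = unphased, 1/2 = haplotype track


@dataclass
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # inclusive; end == start - 1 marks a zero-length virtual segment
    virtual: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class Edge:
    kind: str
    u: Node
    v: Node
    multiplicity: int | None = None  # None = unset
    sv: SVCall | None = None
    #: haplotype-expanded graphs: parallel candidate edges sharing a group id
    #: must sum to the group total (the total-graph multiplicity)
    group: int | None = None

    @property
    def is_loop(self) -> bool:
        return self.u == self.v

    def other(self, node: Node) -> Node:
        return self.v if node == self.u else self.u

    def incidence(self, node: Node) -> int:
        return (self.u == node) + (self.v == node)


@dataclass
class BreakpointGraph:
    """Segments tiling each chromosome plus the edge multiset over their
    head/tail nodes. ``node_edges`` indexes edges by incident node."""

    segments: list[Segment] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    telomeric: set[Node] = field(default_factory=set)
    node_edges: dict[Node, list[int]] = field(default_factory=dict)
    #: per-segment CN annotation (CNSegment), attached by the refinement driver
    cn: dict[int, object] = field(default_factory=dict)
    #: group id -> required total multiplicity (haplotype-expanded graphs)
    group_totals: dict[int, int] = field(default_factory=dict)

    # ---- construction helpers -------------------------------------------
    def add_edge(self, edge: Edge) -> int:
        idx = len(self.edges)
        self.edges.append(edge)
        self.node_edges.setdefault(edge.u, []).append(idx)
        if edge.v != edge.u:
            self.node_edges.setdefault(edge.v, []).append(idx)
        return idx

    def nodes(self) -> Iterable[Node]:
        return self.node_edges.keys()

    # ---- lookups ---------------------------------------------------------
    def segment_edge(self, node: Node) -> Edge | None:
        i = self.segment_edge_index(node)
        return self.edges[i] if i is not None else None

    def segment_edge_index(self, node: Node) -> int | None:
        for i in self.node_edges.get(node, []):
            if self.edges[i].kind == SEGMENT:
                return i
        return None

    def reference_edge(self, node: Node) -> Edge | None:
        """The reference edge at a node (None if absent; if the node carries
        several — a collapsed balanced node in an expanded graph — the first
        is returned; use reference_edges for all of them)."""
        for i in self.node_edges.get(node, []):
            e = self.edges[i]
            if e.kind == REFERENCE:
                return e
        return None

    def reference_edges(self, node: Node) -> list[Edge]:
        return [
            self.edges[i]
            for i in self.node_edges.get(node, [])
            if self.edges[i].kind == REFERENCE
        ]

    def sv_edges(self, node: Node) -> list[Edge]:
        return [
            self.edges[i]
            for i in self.node_edges.get(node, [])
            if self.edges[i].kind == SV
        ]

    def adj_r(self, node: Node) -> Node | None:
        """Node across the reference edge (the reference-adjacent segment end)."""
        e = self.reference_edge(node)
        return e.other(node) if e is not None else None

    def balance_residual(self, node: Node) -> int:
        """mu(e_s) - mu(e_r) - sum mu(v); requires all multiplicities set."""
        seg = self.segment_edge(node)
        total = seg.multiplicity if seg else 0
        r = sum(e.multiplicity * e.incidence(node) for e in self.reference_edges(node))
        vsum = sum(e.multiplicity * e.incidence(node) for e in self.sv_edges(node))
        return total - r - vsum

    def is_balanced(self, node: Node) -> bool:
        return node in self.telomeric or self.balance_residual(node) == 0

    def unbalanced_nodes(self) -> list[Node]:
        return [
            n
            for n in self.node_edges
            if n not in self.telomeric and self.balance_residual(n) != 0
        ]

    def sv_edge_list(self) -> list[Edge]:
        return [e for e in self.edges if e.kind == SV]

    def segment_edge_of(self, seg: int, hap: int = 0) -> Edge | None:
        return self.segment_edge(Node(seg, HEAD, hap))


def _boundary_cuts(calls: list[SVCall], cn_breakpoints: dict[str, Iterable[int]],
                   chrom_lengths: dict[str, int]) -> dict[str, set[int]]:
    """Collect 'cut after position p' boundaries per chromosome.

    A tail breakend at p ends a segment at p (cut at p); a head breakend at
    p starts a segment at p (cut at p-1). CN breakpoints are start
    coordinates (cut at p-1). Coincident SV/CN boundaries deduplicate."""
    cuts: dict[str, set[int]] = {c: set() for c in chrom_lengths}
    for call in calls:
        for bp in (call.bp_a, call.bp_b):
            if bp.chrom not in chrom_lengths or not (1 <= bp.pos <= chrom_lengths[bp.chrom]):
                raise ValueError(
                    f"SV breakpoint {bp.chrom}:{bp.pos} outside reference "
                    f"(call {call.key})"
                )
            cut = bp.pos if bp.side == TAIL else bp.pos - 1
            if 1 <= cut < chrom_lengths[bp.chrom]:
                cuts[bp.chrom].add(cut)
    for chrom, coords in cn_breakpoints.items():
        if chrom not in chrom_lengths:
            continue
        for p in coords:
            cut = p - 1
            if 1 <= cut < chrom_lengths[chrom]:
                cuts[chrom].add(cut)
    return cuts


def build_initial_graph(
    calls: list[SVCall],
    cn_breakpoints: dict[str, Iterable[int]] | None,
    chrom_lengths: dict[str, int],
) -> BreakpointGraph:
    """Construct the initial breakpoint graph from SV calls and CN
    breakpoints.

    Segments partition each chromosome at the union of SV and CN
    breakpoints; reference edges join consecutive segments; one SV edge is
    attached per call at the nodes matching its orientation; chromosome ends
    are telomeric. All multiplicities start unset. Virtual zero-length
    segments are inserted where two SV breakpoints are exactly reciprocal
    (a tail breakend at p and a head breakend at p+1).
    """
    cn_breakpoints = cn_breakpoints or {}
    cuts = _boundary_cuts(calls, cn_breakpoints, chrom_lengths)

    # reciprocal SV breakpoints: tail@p plus head@p+1 from SV calls
    tail_bps: dict[str, set[int]] = {}
    head_bps: dict[str, set[int]] = {}
    for call in calls:
        for bp in (call.bp_a, call.bp_b):
            (tail_bps if bp.side == TAIL else head_bps).setdefault(bp.chrom, set()).add(bp.pos)
    virtual_at: dict[str, set[int]] = {
        chrom: {p for p in tail_bps.get(chrom, set()) if p + 1 in head_bps.get(chrom, set())}
        for chrom in chrom_lengths
    }

    g = BreakpointGraph()
    head_lookup: dict[tuple[str, int], int] = {}  # (chrom, start) -> seg id
    tail_lookup: dict[tuple[str, int], int] = {}  # (chrom, end) -> seg id

    for chrom in sorted(chrom_lengths, key=_chrom_key):
        length = chrom_lengths[chrom]
        ends = sorted(cuts.get(chrom, set())) + [length]
        start = 1
        chrom_segs: list[int] = []
        for end in ends:
            sid = len(g.segments)
            g.segments.append(Segment(chrom, start, end))
            # real segment wins the head/tail coordinate lookups; the
            # virtual twin is registered afterwards where needed
            head_lookup[(chrom, start)] = sid
            tail_lookup[(chrom, end)] = sid
            chrom_segs.append(sid)
            if end in virtual_at.get(chrom, set()):
                vid = len(g.segments)
                g.segments.append(Segment(chrom, end + 1, end, virtual=True))
                chrom_segs.append(vid)
            start = end + 1
        for sid in chrom_segs:
            g.add_edge(Edge(SEGMENT, Node(sid, HEAD), Node(sid, TAIL)))
        for a, b in zip(chrom_segs, chrom_segs[1:]):
            g.add_edge(Edge(REFERENCE, Node(a, TAIL), Node(b, HEAD)))
        g.telomeric.add(Node(chrom_segs[0], HEAD))
        g.telomeric.add(Node(chrom_segs[-1], TAIL))

    for call in calls:
        nodes = []
        for bp in (call.bp_a, call.bp_b):
            if bp.side == TAIL:
                sid = tail_lookup.get((bp.chrom, bp.pos))
            else:
                sid = head_lookup.get((bp.chrom, bp.pos))
            if sid is None:
                raise ValueError(
                    f"breakend {bp.chrom}:{bp.pos}/{bp.side} does not fall on a "
                    f"segment boundary (call {call.key})"
                )
            nodes.append(Node(sid, bp.side))
        g.add_edge(Edge(SV, nodes[0], nodes[1], sv=call))
    return g
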