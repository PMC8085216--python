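"""Allele-specific breakpoint graph construction.

Segments whose selected ASCN split is imbalanced (a1 != a2) are expanded
into two haplotype-labelled node pairs carrying the two allele-specific
copy numbers; balanced segments stay collapsed with their total CN. The
assignment of the ordered pair onto the two temporary haplotype tracks, and
the switch of a low-confidence segment to an alternative split (at a
penalty eps(s)/2 per node, eps = rank of the alternative's likelihood
score), are chosen to minimise the balance objective. Runs of consecutive
imbalanced segments are solved exactly (exhaustive enumeration) when short
and by a left-to-right greedy pass on long runs; reference- and SV-edge
multiplicities on the expanded graph are then solved by the balance integer
program, with each original SV's multiplicity distributed across its
haplotype-track candidate edges (they sum to the total multiplicity).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ascn import ASCNSelection, ASCNState, enumerate_allelic_states
from .balance import solve_graph
from .graph import (
    HEAD,
    REFERENCE,
    SEGMENT,
    SV,
    TAIL,
    BreakpointGraph,
    Edge,
    Node,
)

#: run length up to which the track assignment is solved exhaustively
EXACT_RUN_LIMIT = 10
#: alternative ASCN states considered for a low-confidence segment
MAX_ALTERNATIVES = 3


@dataclass
class SegAllele:
    """Chosen split and track orientation of one segment: track 1 carries
    ``c1`` copies, track 2 carries ``c2``; balanced segments stay collapsed."""

    seg: int
    c1: int
    c2: int
    epsilon: int = 0
    state: ASCNState | None = None

    @property
    def balanced(self) -> bool:
        return self.c1 == self.c2

    @property
    def total(self) -> int:
        return self.c1 + self.c2


@dataclass
class AlleleGraphResult:
    graph: BreakpointGraph
    assignments: dict[int, SegAllele]
    runs: list[list[int]] = field(default_factory=list)
    penalty: float = 0.0


def _options(
    mu: int, selection: ASCNSelection | None
) -> list[tuple[int, int, int, ASCNState | None]]:
    """Candidate (c1, c2, eps, state) choices for one segment."""
    if selection is None:
        # no SNP information: the most balanced split, no penalty
        a = mu // 2
        states = [(a, mu - a, 0, None)]
        if a != mu - a:
            states.append((mu - a, a, 0, None))
        return states
    ranked = selection.ranked
    if selection.confident:
        ranked = ranked[:1]
    out: list[tuple[int, int, int, ASCNState | None]] = []
    for rank, st in enumerate(ranked[:MAX_ALTERNATIVES]):
        if st.a1 + st.a2 != mu:
            continue
        out.append((st.a1, st.a2, rank, st))
        if st.a1 != st.a2:
            out.append((st.a2, st.a1, rank, st))
    if not out:
        a = mu // 2
        out = [(a, mu - a, 0, None)]
        if a != mu - a:
            out.append((mu - a, a, 0, None))
    return out


def junction_cost(
    x: tuple[int, int], y: tuple[int, int], sv_tail: int, sv_head: int
) -> int:
    """Local per-haplotype imbalance between consecutive segments after
    maximally preserving reference edges, less what incident SV copies can
    absorb at either side of the junction."""
    excess_tail = sum(max(x[t] - y[t], 0) for t in (0, 1))
    excess_head = sum(max(y[t] - x[t], 0) for t in (0, 1))
    return max(excess_tail - sv_tail, 0) + max(excess_head - sv_head, 0)


def greedy_run_solver(
    options: list[list[tuple[int, int, int, ASCNState | None]]],
    sv_caps: list[tuple[int, int]],
) -> tuple[list[tuple[int, int, int, ASCNState | None]], int]:
    """Left-to-right greedy pass: at each segment pick the option minimising
    the local junction cost (plus its eps penalty) against the previous
    choice; ties keep the previous orientation.

    ``sv_caps[k]`` = (SV multiplicity at the tail of segment k, at the head
    of segment k+1) for junction k.
    """
    first = min(options[0], key=lambda o: (o[2], (o[0], o[1])))
    chosen = [first]
    cost = first[2]
    for k in range(1, len(options)):
        prev = chosen[-1]
        prev_orient = prev[0] <= prev[1]
        sv_tail, sv_head = sv_caps[k - 1]

        def rank_key(opt):
            c = junction_cost((prev[0], prev[1]), (opt[0], opt[1]), sv_tail, sv_head)
            same_orient = (opt[0] <= opt[1]) == prev_orient
            return (c + opt[2], 0 if same_orient else 1, (opt[0], opt[1]))

        best = min(options[k], key=rank_key)
        cost += junction_cost((prev[0], prev[1]), (best[0], best[1]), sv_tail, sv_head)
        cost += best[2]
        chosen.append(best)
    return chosen, cost


def exhaustive_run_solver(
    options: list[list[tuple[int, int, int, ASCNState | None]]],
    sv_caps: list[tuple[int, int]],
) -> tuple[list[tuple[int, int, int, ASCNState | None]], int]:
    """Exact minimiser of the same objective by full enumeration."""
    best_choice: list | None = None
    best_cost = None

    def recurse(k: int, prefix: list, cost: int) -> None:
        nonlocal best_choice, best_cost
        if best_cost is not None and cost >= best_cost:
            return
        if k == len(options):
            best_cost = cost
            best_choice = list(prefix)
            return
        for opt in sorted(options[k], key=lambda o: ((o[0], o[1]), o[2])):
            extra = opt[2]
            if k > 0:
                prev = prefix[-1]
                extra += junction_cost(
                    (prev[0], prev[1]), (opt[0], opt[1]), *sv_caps[k - 1]
                )
            prefix.append(opt)
            recurse(k + 1, prefix, cost + extra)
            prefix.pop()

    recurse(0, [], 0)
    return best_choice, best_cost


def _sv_multiplicity_at(graph: BreakpointGraph, node: Node) -> int:
    return sum(
        (e.multiplicity or 0) * e.incidence(node) for e in graph.sv_edges(node)
    )


def build_allele_graph(
    graph: BreakpointGraph,
    selections: dict[int, ASCNSelection | None],
    max_cn: int = 100,
) -> AlleleGraphResult:
    """Expand a solved total-CN breakpoint graph into its allele-specific
    form given per-segment ASCN selections."""
    mu_of: dict[int, int] = {}
    for sid in range(len(graph.segments)):
        e = graph.segment_edge(Node(sid, HEAD))
        if e is None or e.multiplicity is None:
            raise ValueError("total graph multiplicities must be solved first")
        mu_of[sid] = e.multiplicity

    # runs of consecutive imbalanced segments per chromosome
    assignments: dict[int, SegAllele] = {}
    runs: list[list[int]] = []
    penalty = 0.0
    by_chrom: dict[str, list[int]] = {}
    for sid, seg in enumerate(graph.segments):
        by_chrom.setdefault(seg.chrom, []).append(sid)

    def must_imbalanced(sid: int) -> bool:
        sel = selections.get(sid)
        if sel is not None and sel.confident:
            return sel.best.imbalanced
        return mu_of[sid] % 2 == 1 or (
            sel is not None and sel.best.imbalanced
        )

    for chrom, sids in by_chrom.items():
        run: list[int] = []
        for sid in sids:
            if must_imbalanced(sid):
                run.append(sid)
            else:
                if run:
                    runs.append(run)
                    run = []
                mu = mu_of[sid]
                sel = selections.get(sid)
                st = sel.best if sel is not None else None
                assignments[sid] = SegAllele(sid, mu // 2, mu - mu // 2, 0, st)
        if run:
            runs.append(run)

    for run in runs:
        options = [_options(mu_of[sid], selections.get(sid)) for sid in run]
        sv_caps = []
        for a, b in zip(run, run[1:]):
            sv_caps.append(
                (
                    _sv_multiplicity_at(graph, Node(a, TAIL)),
                    _sv_multiplicity_at(graph, Node(b, HEAD)),
                )
            )
        solver = (
            exhaustive_run_solver if len(run) <= EXACT_RUN_LIMIT else greedy_run_solver
        )
        chosen, cost = solver(options, sv_caps)
        penalty += sum(o[2] for o in chosen)
        for sid, (c1, c2, eps, st) in zip(run, chosen):
            assignments[sid] = SegAllele(sid, c1, c2, eps, st)

    ag = _expand(graph, assignments, max_cn)
    return AlleleGraphResult(
        graph=ag, assignments=assignments, runs=runs, penalty=penalty
    )


def expanded_nodes(assignment: SegAllele, side: str) -> list[Node]:
    if assignment.balanced:
        return [Node(assignment.seg, side, 0)]
    return [Node(assignment.seg, side, 1), Node(assignment.seg, side, 2)]


def _expand(
    graph: BreakpointGraph,
    assignments: dict[int, SegAllele],
    max_cn: int,
    force_two_tracks: bool = False,
) -> BreakpointGraph:
    """Build the expanded graph and solve its edge multiplicities."""
    ag = BreakpointGraph(segments=list(graph.segments), cn=dict(graph.cn))

    def tracks(sid: int, side: str) -> list[Node]:
        a = assignments[sid]
        if force_two_tracks or not a.balanced:
            return [Node(sid, side, 1), Node(sid, side, 2)]
        return [Node(sid, side, 0)]

    for sid, a in sorted(assignments.items()):
        if force_two_tracks or not a.balanced:
            ag.add_edge(Edge(SEGMENT, Node(sid, HEAD, 1), Node(sid, TAIL, 1), a.c1))
            ag.add_edge(Edge(SEGMENT, Node(sid, HEAD, 2), Node(sid, TAIL, 2), a.c2))
        else:
            ag.add_edge(Edge(SEGMENT, Node(sid, HEAD, 0), Node(sid, TAIL, 0), a.total))

    for e in graph.edges:
        if e.kind == SEGMENT:
            continue
        if e.kind == REFERENCE:
            us = tracks(e.u.seg, e.u.side)
            vs = tracks(e.v.seg, e.v.side)
            if len(us) == 2 and len(vs) == 2:
                # track-preserving reference edges within a run
                ag.add_edge(Edge(REFERENCE, us[0], vs[0]))
                ag.add_edge(Edge(REFERENCE, us[1], vs[1]))
            else:
                for u in us:
                    for v in vs:
                        ag.add_edge(Edge(REFERENCE, u, v))

    gid = 0
    for e in graph.edges:
        if e.kind != SV:
            continue
        mult = e.multiplicity or 0
        if mult <= 0:
            continue
        us = tracks(e.u.seg, e.u.side)
        vs = tracks(e.v.seg, e.v.side)
        combos = []
        seen = set()
        for u in us:
            for v in vs:
                key = frozenset([u, v]) if e.u == e.v else (u, v)
                if key in seen:
                    continue
                seen.add(key)
                combos.append((u, v))
        if len(combos) == 1:
            ag.add_edge(Edge(SV, combos[0][0], combos[0][1], mult, sv=e.sv))
        else:
            ag.group_totals[gid] = mult
            for u, v in combos:
                ag.add_edge(Edge(SV, u, v, sv=e.sv, group=gid))
            gid += 1

    # telomeres transfer to every track of the end segments
    for node in graph.telomeric:
        for n in tracks(node.seg, node.side):
            ag.telomeric.add(n)

    solve_graph(ag, max_cn=max_cn)
    return ag
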