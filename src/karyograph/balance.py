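"""The copy-number balance integer program.

Edge multiplicities are solved per *interrelated subset* of nodes: the BFS
closure that always crosses reference and SV edges but crosses a segment
edge only when the segment's CN is not confident. Within a subset the
program

    minimise   sum_s ( mu(e_s(s)) - mu(e_r(s)) - sum_v mu(v) )
    subject to mu(e_s(s)) >= mu(e_r(s)) + sum_v mu(v)
               sum_v mu(v) <= | mu(e_s(s)) - mu(e_s(Adj_r(s))) |
               mu(e_s(s)) fixed at CN(s)            (confident, >=50 bp)
               mu(e_s(s)) in {CN(s), alt CN(s)}     (low-confidence)
               mu(e_s(s)) in [0, max CN]            (<50 bp / virtual / no depth)

is solved exactly with HiGHS (``scipy.optimize.milp``). Ties are broken
lexicographically by three sequential solves: (1) minimum total imbalance,
(2) maximum total SV multiplicity at that imbalance — this is what keeps
simple inversions and balanced translocations from collapsing to the null
solution — and (3) segment multiplicities closest to the initial CNs.

The absolute-value cap with variable segment edges is encoded exactly with
one sign binary per node (big-M disjunction). SV edges left at multiplicity
zero are false positives and are pruned before the next iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .cnsegment import CNSegment, MIN_CONFIDENT_SIZE
from .graph import REFERENCE, SEGMENT, SV, BreakpointGraph, Edge, Node
from .svcalls import SVCall

FIXED = "fixed"
BINARY = "binary"
FREE = "free"


def segment_domain(graph: BreakpointGraph, seg: int, max_cn: int = 100):
    """Domain of a segment edge: ('fixed', cn) / ('binary', cn, alt) /
    ('free', 0, max_cn)."""
    segment = graph.segments[seg]
    info: CNSegment | None = graph.cn.get(seg)
    if segment.virtual or segment.length < MIN_CONFIDENT_SIZE:
        return (FREE, 0, max_cn)
    if info is None or info.no_depth or info.integer_cn is None:
        return (FREE, 0, max_cn)
    if info.confident:
        return (FIXED, info.integer_cn, info.integer_cn)
    alt = info.alternative_cn if info.alternative_cn is not None else info.integer_cn
    return (BINARY, info.integer_cn, alt)


def node_confident(graph: BreakpointGraph, node: Node, max_cn: int = 100) -> bool:
    pre = graph.segment_edge(node)
    if pre is not None and pre.multiplicity is not None:
        return True
    return segment_domain(graph, node.seg, max_cn)[0] == FIXED


@dataclass
class InterrelatedSubset:
    nodes: set[Node]
    frozen_cns: dict[Node, int] = field(default_factory=dict)
    variable_nodes: set[Node] = field(default_factory=set)


def _neighbours(graph: BreakpointGraph, node: Node, cross_segment: bool):
    for i in graph.node_edges.get(node, []):
        e = graph.edges[i]
        if e.kind == SEGMENT and not cross_segment:
            continue
        yield e.other(node)


def find_interrelated_subset(
    graph: BreakpointGraph, start: Node, max_cn: int = 100
) -> InterrelatedSubset:
    """Closure of {start} under the expansion rules; deterministic (the
    closure is unique whatever the BFS order, candidates are processed in
    (segment, side) order)."""
    seen = {start}
    queue = [start]
    while queue:
        queue.sort()
        node = queue.pop(0)
        cross = not node_confident(graph, node, max_cn)
        for nb in _neighbours(graph, node, cross_segment=cross):
            if nb not in seen:
                seen.add(nb)
                queue.append(nb)
    sub = InterrelatedSubset(nodes=seen)
    for n in seen:
        kind, cn, _ = segment_domain(graph, n.seg, max_cn)
        if kind == FIXED:
            sub.frozen_cns[n] = cn
        else:
            sub.variable_nodes.add(n)
    return sub


def interrelated_partition(graph: BreakpointGraph, max_cn: int = 100) -> list[InterrelatedSubset]:
    """All maximal interrelated subsets (they tile the node set; no two
    share a variable edge)."""
    seen: set[Node] = set()
    subsets = []
    for node in sorted(graph.node_edges):
        if node in seen:
            continue
        sub = find_interrelated_subset(graph, node, max_cn)
        seen |= sub.nodes
        subsets.append(sub)
    return subsets


@dataclass
class IlpSolution:
    multiplicities: dict[int, int]  # edge index -> multiplicity
    objective: int
    sv_total: int
    deviation: int


class _Milp:
    """Small dense MILP builder over scipy's HiGHS interface."""

    def __init__(self) -> None:
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.rows: list[dict[int, float]] = []
        self.row_lb: list[float] = []
        self.row_ub: list[float] = []

    def var(self, lb: float, ub: float) -> int:
        self.lb.append(lb)
        self.ub.append(ub)
        return len(self.lb) - 1

    def constrain(self, coeffs: dict[int, float], lb: float, ub: float) -> None:
        self.rows.append(dict(coeffs))
        self.row_lb.append(lb)
        self.row_ub.append(ub)

    def solve(self, objective: dict[int, float], sense: int = 1):
        n = len(self.lb)
        if n == 0:
            return np.zeros(0, dtype=int), 0.0
        c = np.zeros(n)
        for i, v in objective.items():
            c[i] = sense * v
        A = np.zeros((len(self.rows), n))
        for r, row in enumerate(self.rows):
            for i, v in row.items():
                A[r, i] = v
        constraints = (
            LinearConstraint(A, np.array(self.row_lb), np.array(self.row_ub))
            if self.rows
            else ()
        )
        res = milp(
            c,
            constraints=constraints,
            bounds=Bounds(np.array(self.lb), np.array(self.ub)),
            integrality=np.ones(n),
        )
        if not res.success:
            raise RuntimeError(f"integer program failed: {res.message}")
        return np.rint(res.x).astype(int), sense * float(res.fun)


def _build_program(graph: BreakpointGraph, subset: InterrelatedSubset, max_cn: int):
    """Shared constraint system for the three sequential solves.

    Returns (milp builder, edge_var map, seg expressions, metadata)."""
    m = _Milp()
    edge_var: dict[int, int] = {}  # edge index -> variable id (ref/sv edges)
    # (seg, hap) -> const + coeffs expression for the segment-edge multiplicity
    seg_expr: dict[tuple[int, int], tuple[float, dict[int, float]]] = {}
    binary_dev: dict[tuple[int, int], tuple[int, int]] = {}  # -> (delta var, |alt-cn|)
    free_cn: dict[tuple[int, int], int] = {}  # free segs with an initial CN estimate

    seg_keys = {(n.seg, n.hap) for n in subset.nodes}
    internal_edges: set[int] = set()
    for n in subset.nodes:
        for i in graph.node_edges.get(n, []):
            e = graph.edges[i]
            if e.kind == SEGMENT:
                continue
            if e.u in subset.nodes and e.v in subset.nodes:
                internal_edges.add(i)

    for key in sorted(seg_keys):
        seg, hap = key
        pre = graph.segment_edge(Node(seg, "head", hap))
        if pre is not None and pre.multiplicity is not None:
            # expanded allele/haplotype graphs carry pre-set segment edges
            seg_expr[key] = (float(pre.multiplicity), {})
            continue
        kind, cn, alt = segment_domain(graph, seg, max_cn)
        if kind == FIXED or (kind == BINARY and alt == cn):
            seg_expr[key] = (float(cn), {})
        elif kind == BINARY:
            d = m.var(0, 1)
            seg_expr[key] = (float(cn), {d: float(alt - cn)})
            binary_dev[key] = (d, abs(alt - cn))
        else:
            v = m.var(0, max_cn)
            seg_expr[key] = (0.0, {v: 1.0})
            info = graph.cn.get(seg)
            if info is not None and getattr(info, "integer_cn", None) is not None:
                free_cn[key] = info.integer_cn
            elif graph.segments[seg].virtual:
                # a zero-length virtual segment inherits its flank's CN so
                # the deviation tie-break anchors the adjacent multiplicities
                for nb in (seg - 1, seg + 1):
                    flank = graph.cn.get(nb)
                    if (
                        0 <= nb < len(graph.segments)
                        and graph.segments[nb].chrom == graph.segments[seg].chrom
                        and flank is not None
                        and getattr(flank, "integer_cn", None) is not None
                    ):
                        free_cn[key] = flank.integer_cn
                        break

    groups: dict[int, list[int]] = {}
    fixed_edges: dict[int, int] = {}
    for i in sorted(internal_edges):
        e = graph.edges[i]
        if e.multiplicity is not None:
            fixed_edges[i] = e.multiplicity  # pre-set adjacency: a constant
            continue
        ub = graph.group_totals.get(e.group, max_cn) if e.group is not None else max_cn
        edge_var[i] = m.var(0, ub)
        if e.group is not None:
            groups.setdefault(e.group, []).append(edge_var[i])
    # parallel candidate edges of one original SV must sum to its multiplicity
    for gid, gvars in groups.items():
        total = graph.group_totals[gid]
        m.constrain({v: 1.0 for v in gvars}, total, total)

    def node_terms(node: Node):
        """(const, coeffs) for mu(e_s) - mu(e_r) - sum mu(v) at node."""
        const, coeffs = seg_expr[(node.seg, node.hap)]
        coeffs = dict(coeffs)
        for i in graph.node_edges.get(node, []):
            e = graph.edges[i]
            if e.kind == SEGMENT:
                continue
            if i in fixed_edges:
                const -= float(fixed_edges[i] * e.incidence(node))
            elif i in edge_var:
                coeffs[edge_var[i]] = coeffs.get(edge_var[i], 0.0) - float(
                    e.incidence(node)
                )
        return const, coeffs

    balance_nodes = [n for n in sorted(subset.nodes) if n not in graph.telomeric]
    imb_terms: list[tuple[float, dict[int, float]]] = []
    for node in balance_nodes:
        const, coeffs = node_terms(node)
        # first constraint: imbalance >= 0
        m.constrain(coeffs, -const, np.inf)
        imb_terms.append((const, coeffs))

        # SV cap: sum_v mu(v) <= |mu(e_s(s)) - mu(e_s(Adj_r(s)))|
        sv_coeffs: dict[int, float] = {}
        sv_fixed = 0.0
        for i in graph.node_edges.get(node, []):
            e = graph.edges[i]
            if e.kind != SV:
                continue
            if i in edge_var:
                sv_coeffs[edge_var[i]] = sv_coeffs.get(edge_var[i], 0.0) + float(
                    e.incidence(node)
                )
            elif i in fixed_edges:
                sv_fixed += float(fixed_edges[i] * e.incidence(node))
        if not sv_coeffs:
            continue
        refs = graph.reference_edges(node)
        if len(refs) != 1:
            # collapsed balanced nodes in expanded graphs carry two
            # reference edges; the difference cap is not defined there
            continue
        adj = refs[0].other(node)
        if (adj.seg, adj.hap) not in seg_expr or adj.hap != node.hap:
            # comparing a haplotype track against a collapsed total CN is
            # meaningless; the cap applies within one track only
            continue
        a_const, a_coeffs = seg_expr[(node.seg, node.hap)]
        b_const, b_coeffs = seg_expr[(adj.seg, adj.hap)]
        diff_coeffs: dict[int, float] = {}
        for i, v in a_coeffs.items():
            diff_coeffs[i] = diff_coeffs.get(i, 0.0) + v
        for i, v in b_coeffs.items():
            diff_coeffs[i] = diff_coeffs.get(i, 0.0) - v
        diff_const = a_const - b_const
        if not diff_coeffs:
            # constant bound
            m.constrain(sv_coeffs, -np.inf, abs(diff_const) - sv_fixed)
            continue
        big_m = (len(sv_coeffs) + 2.0) * max_cn + abs(diff_const) + sv_fixed
        d = m.var(0, 1)
        # sum_v <= (a-b) + M(1-d)  ->  sum_v - (a-b) + M d <= M
        row = dict(sv_coeffs)
        for i, v in diff_coeffs.items():
            row[i] = row.get(i, 0.0) - v
        row[d] = big_m
        m.constrain(row, -np.inf, big_m + diff_const - sv_fixed)
        # sum_v <= (b-a) + M d
        row2 = dict(sv_coeffs)
        for i, v in diff_coeffs.items():
            row2[i] = row2.get(i, 0.0) + v
        row2[d] = -big_m
        m.constrain(row2, -np.inf, -diff_const - sv_fixed)
    return m, edge_var, seg_expr, binary_dev, free_cn, imb_terms


def _merge(target: dict[int, float], terms: dict[int, float], scale: float = 1.0) -> None:
    for i, v in terms.items():
        target[i] = target.get(i, 0.0) + scale * v


def solve_cn_balance(
    subset: InterrelatedSubset,
    graph: BreakpointGraph,
    max_cn: int = 100,
    tie_break: bool = True,
) -> IlpSolution:
    """Exact lexicographic solution of the balance program on one subset:
    sequential solves for imbalance, SV total, then CN deviation."""
    m, edge_var, seg_expr, binary_dev, free_cn, imb_terms = _build_program(
        graph, subset, max_cn
    )
    obj: dict[int, float] = {}
    obj_const = 0.0
    for const, coeffs in imb_terms:
        obj_const += const
        _merge(obj, coeffs)
    x, z1 = m.solve(obj)
    objective = int(round(z1 + obj_const))

    sv_vars = [var for i, var in sorted(edge_var.items()) if graph.edges[i].kind == SV]
    if tie_break:
        # fix total imbalance at its optimum, then recall as many SVs as
        # possible: maximise the number of SV edges with multiplicity >= 1
        # (this is what prevents null solutions for simple inversions and
        # balanced translocations without inflating their multiplicities)
        m.constrain(obj, z1, z1)
        plain_sv = [
            var
            for i, var in sorted(edge_var.items())
            if graph.edges[i].kind == SV and graph.edges[i].group is None
        ]
        if plain_sv:
            pos_obj: dict[int, float] = {}
            for var in plain_sv:
                y = m.var(0, 1)
                m.constrain({y: 1.0, var: -1.0}, -np.inf, 0.0)  # y <= mu
                pos_obj[y] = 1.0
            x, z2 = m.solve(pos_obj, sense=-1)
            m.constrain(pos_obj, z2, z2)
        # with both fixed, minimise deviation from the initial CNs
        dev_obj: dict[int, float] = {}
        for key, (d, w) in binary_dev.items():
            dev_obj[d] = dev_obj.get(d, 0.0) + float(w)
        for key, cn0 in free_cn.items():
            (_, coeffs) = seg_expr[key]
            var = next(iter(coeffs))
            t = m.var(0, max_cn + cn0)
            m.constrain({var: 1.0, t: -1.0}, -np.inf, cn0)
            m.constrain({var: -1.0, t: -1.0}, -np.inf, -cn0)
            dev_obj[t] = dev_obj.get(t, 0.0) + 1.0
        if dev_obj:
            x, z3 = m.solve(dev_obj)
            deviation = int(round(z3))
            m.constrain(dev_obj, z3, z3)
        else:
            deviation = 0
        grouped_sv = [
            (i, var)
            for i, var in sorted(edge_var.items())
            if graph.edges[i].group is not None
        ]
        if grouped_sv:
            # concentrate each SV's multiplicity on as few haplotype-track
            # candidates as possible (an SV arises on one haplotype)
            conc_obj: dict[int, float] = {}
            for i, var in grouped_sv:
                ub = graph.group_totals.get(graph.edges[i].group, max_cn)
                z = m.var(0, 1)
                m.constrain({var: 1.0, z: -float(max(ub, 1))}, -np.inf, 0.0)
                conc_obj[z] = 1.0
            x, zc = m.solve(conc_obj)
            m.constrain(conc_obj, zc, zc)
        if grouped_sv:
            # finally, split reference flow out of collapsed balanced nodes
            # as evenly as possible across the haplotype tracks (avoids
            # spurious circular fragments among remaining optima)
            even_obj: dict[int, float] = {}
            for node in sorted(subset.nodes):
                if node.hap != 0:
                    continue
                ref_vars = [
                    edge_var[i]
                    for i in graph.node_edges.get(node, [])
                    if graph.edges[i].kind == REFERENCE and i in edge_var
                ]
                if len(ref_vars) == 2:
                    t = m.var(0, 2 * max_cn)
                    m.constrain({ref_vars[0]: 1.0, ref_vars[1]: -1.0, t: -1.0}, -np.inf, 0.0)
                    m.constrain({ref_vars[0]: -1.0, ref_vars[1]: 1.0, t: -1.0}, -np.inf, 0.0)
                    even_obj[t] = 1.0
            if even_obj:
                x, _ = m.solve(even_obj)
        sv_total = int(sum(x[v] for v in sv_vars))
    else:
        sv_total = int(sum(x[v] for v in sv_vars))
        deviation = int(sum(w * x[d] for d, w in binary_dev.values()))

    mults: dict[int, int] = {i: int(x[var]) for i, var in edge_var.items()}
    for (seg, hap), (const, coeffs) in seg_expr.items():
        val = const + sum(c * x[i] for i, c in coeffs.items())
        idx = graph.segment_edge_index(Node(seg, "head", hap))
        if idx is not None:
            mults[idx] = int(round(val))
    return IlpSolution(
        multiplicities=mults,
        objective=objective,
        sv_total=sv_total,
        deviation=deviation,
    )


def resolve_ties(
    subset: InterrelatedSubset, graph: BreakpointGraph, max_cn: int = 100
) -> IlpSolution:
    """Lexicographic tie-breaking (bound sweeps realised as sequential exact
    solves); identical to ``solve_cn_balance`` with tie_break=True."""
    return solve_cn_balance(subset, graph, max_cn=max_cn, tie_break=True)


def solve_graph(graph: BreakpointGraph, max_cn: int = 100) -> list[IlpSolution]:
    """Solve every interrelated subset and write multiplicities onto the
    graph's edges."""
    solutions = []
    for subset in interrelated_partition(graph, max_cn):
        sol = solve_cn_balance(subset, graph, max_cn=max_cn)
        for idx, mult in sol.multiplicities.items():
            graph.edges[idx].multiplicity = mult
        solutions.append(sol)
    return solutions


def prune_zero_multiplicity(
    graph: BreakpointGraph,
) -> tuple[list[SVCall], list[SVCall]]:
    """Split the graph's SV calls into (retained, removed) by solved edge
    multiplicity; zero-multiplicity SVs are false positives."""
    retained, removed = [], []
    for e in graph.sv_edge_list():
        if e.multiplicity is None:
            raise ValueError("graph multiplicities are unset; solve first")
        (retained if e.multiplicity >= 1 else removed).append(e.sv)
    return retained, removed
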