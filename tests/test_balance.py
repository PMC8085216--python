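"""Copy-number balance integer program: balance condition, tie-breaking,
interrelated subsets, pruning — checked against exhaustive enumeration."""

import itertools

import numpy as np
import pytest

from karyograph.balance import (
    find_interrelated_subset,
    interrelated_partition,
    prune_zero_multiplicity,
    solve_cn_balance,
    solve_graph,
)
from karyograph.cnsegment import CNSegment
from karyograph.graph import HEAD, SV, TAIL, Node, build_initial_graph
from karyograph.svcalls import Breakend, SVCall

from conftest import make_chain_graph


def assert_balanced(g):
    for node in g.node_edges:
        if node not in g.telomeric:
            assert g.balance_residual(node) == 0, node


class TestForcedSolutions:
    def test_multiplicity_forced_by_balance(self):
        # mid segment CN 3 flanked by 2: dup junction must carry mu 2 - 1...
        # node with mu(e_s)=3, mu(e_r)=1 and one sv edge -> mu(v)=2
        g = make_chain_graph([1, 3, 1], [((1, HEAD), (1, TAIL))])
        solve_graph(g)
        (e,) = g.sv_edge_list()
        assert e.multiplicity == 2
        assert_balanced(g)

    def test_spurious_sv_on_flat_background_zeroed(self):
        g = make_chain_graph([2, 2, 2, 2], [((0, TAIL), (3, HEAD))])
        solve_graph(g)
        assert g.sv_edge_list()[0].multiplicity == 0

    def test_deletion_step_gives_unit_multiplicity(self):
        g = make_chain_graph([2, 1, 2], [((0, TAIL), (2, HEAD))])
        solve_graph(g)
        assert g.sv_edge_list()[0].multiplicity == 1
        assert_balanced(g)


class TestReciprocalAndInversion:
    def test_inversion_rescued_at_unit_multiplicity(self):
        c1 = SVCall(Breakend("chr1", 2000, TAIL), Breakend("chr1", 6000, TAIL))
        c2 = SVCall(Breakend("chr1", 2001, HEAD), Breakend("chr1", 6001, HEAD))
        g = build_initial_graph([c1, c2], {}, {"chr1": 10000})
        for i, s in enumerate(g.segments):
            if not s.virtual:
                g.cn[i] = CNSegment(s.chrom, s.start, s.end, integer_cn=2,
                                    posterior=0.99, confident=True, n_bins=100)
        solve_graph(g)
        assert [e.multiplicity for e in g.sv_edge_list()] == [1, 1]
        assert_balanced(g)

    def test_reciprocal_translocation_without_virtual_segment_is_nulled(self):
        # hand-built graph with NO virtual segment: the difference cap
        # forces both reciprocal junction multiplicities to zero
        g = make_chain_graph([2, 2], [], chrom="chr1")
        g2 = make_chain_graph([2, 2], [], chrom="chr2")
        # merge the two chromosomes into one graph
        offset = len(g.segments)
        for s in g2.segments:
            g.segments.append(s)
        for i, cn in g2.cn.items():
            g.cn[offset + i] = cn
        for e in g2.edges:
            e.u = Node(e.u.seg + offset, e.u.side, 0)
            e.v = Node(e.v.seg + offset, e.v.side, 0)
            g.add_edge(e)
        for n in g2.telomeric:
            g.telomeric.add(Node(n.seg + offset, n.side, 0))
        c1 = SVCall(Breakend("chr1", 1000, TAIL), Breakend("chr2", 1001, HEAD))
        c2 = SVCall(Breakend("chr1", 1001, HEAD), Breakend("chr2", 1000, TAIL))
        from karyograph.graph import Edge
        g.add_edge(Edge(SV, Node(0, TAIL), Node(offset + 1, HEAD), sv=c1))
        g.add_edge(Edge(SV, Node(1, HEAD), Node(offset, TAIL), sv=c2))
        solve_graph(g)
        assert [e.multiplicity for e in g.sv_edge_list()] == [0, 0]

    def test_reciprocal_translocation_with_virtual_segment_rescued(self):
        c1 = SVCall(Breakend("chr1", 5000, TAIL), Breakend("chr2", 5001, HEAD))
        c2 = SVCall(Breakend("chr1", 5001, HEAD), Breakend("chr2", 5000, TAIL))
        g = build_initial_graph([c1, c2], {}, {"chr1": 10000, "chr2": 10000})
        assert any(s.virtual for s in g.segments)
        for i, s in enumerate(g.segments):
            if not s.virtual:
                g.cn[i] = CNSegment(s.chrom, s.start, s.end, integer_cn=2,
                                    posterior=0.99, confident=True, n_bins=100)
        solve_graph(g)
        assert all(e.multiplicity >= 1 for e in g.sv_edge_list())
        assert_balanced(g)


class TestInterrelatedSubsets:
    def test_confident_node_blocks_segment_edge_propagation(self):
        g = make_chain_graph([2, 2, 2])
        sub = find_interrelated_subset(g, Node(0, TAIL))
        # crossing reference edges only: tail(0) + head(1), then stop at
        # the confident segment edge of segment 1... head(0) not reachable
        assert Node(1, HEAD) in sub.nodes
        assert Node(1, TAIL) not in sub.nodes
        assert Node(0, HEAD) not in sub.nodes

    def test_low_confidence_chain_is_one_subset(self):
        g = make_chain_graph([2, 2, 2], confident=[False] * 3,
                             alternatives=[3, 3, 3])
        sub = find_interrelated_subset(g, Node(0, HEAD))
        assert len(sub.nodes) == 6

    def test_isolated_confident_segment(self):
        g = make_chain_graph([2])
        sub = find_interrelated_subset(g, Node(0, HEAD))
        assert sub.nodes == {Node(0, HEAD)}

    def test_partition_solves_match_joint_graph(self):
        g = make_chain_graph(
            [2, 3, 2, 1, 2],
            [((1, HEAD), (1, TAIL)), ((2, TAIL), (4, HEAD))],
            confident=[True, False, True, True, True],
            alternatives=[None, 2, None, None, None],
        )
        solve_graph(g)
        first = [e.multiplicity for e in g.edges]
        for e in g.edges:
            e.multiplicity = None
        solve_graph(g)
        assert [e.multiplicity for e in g.edges] == first


# ---------------------------------------------------------------------------
# exhaustive lexicographic oracle
# ---------------------------------------------------------------------------

def oracle_optima(g, max_mult):
    """All optimal assignments by exhaustive enumeration under the same
    lexicographic order: (total imbalance, -positive SV count, CN deviation)."""
    from karyograph.balance import segment_domain

    n_seg = len(g.segments)
    domains = []
    for sid in range(n_seg):
        kind, cn, alt = segment_domain(g, sid)
        if kind == "fixed":
            domains.append([cn])
        elif kind == "binary":
            domains.append(sorted({cn, alt}))
        else:
            domains.append(list(range(max_mult + 1)))
    var_edges = [i for i, e in enumerate(g.edges) if e.kind != "segment"]
    edge_domains = [list(range(max_mult + 1))] * len(var_edges)

    best_key = None
    best = []
    for seg_vals in itertools.product(*domains):
        for edge_vals in itertools.product(*edge_domains):
            mult = dict(zip(var_edges, edge_vals))
            ok = True
            imbalance = 0
            for node in g.node_edges:
                if node in g.telomeric:
                    continue
                mu_s = seg_vals[node.seg]
                mu_r = 0
                sv_sum = 0
                for i in g.node_edges[node]:
                    e = g.edges[i]
                    if e.kind == "reference":
                        mu_r += mult[i] * e.incidence(node)
                    elif e.kind == "sv":
                        sv_sum += mult[i] * e.incidence(node)
                resid = mu_s - mu_r - sv_sum
                if resid < 0:
                    ok = False
                    break
                imbalance += resid
                adj = g.adj_r(node)
                if adj is not None and sv_sum > abs(mu_s - seg_vals[adj.seg]):
                    ok = False
                    break
            if not ok:
                continue
            pos = sum(
                1 for i in var_edges if g.edges[i].kind == "sv" and mult[i] >= 1
            )
            dev = sum(
                abs(seg_vals[s] - g.cn[s].integer_cn)
                for s in range(n_seg)
                if g.cn.get(s) is not None and g.cn[s].integer_cn is not None
                and len(domains[s]) > 1
            )
            key = (imbalance, -pos, dev)
            if best_key is None or key < best_key:
                best_key = key
                best = [(seg_vals, dict(mult))]
            elif key == best_key:
                best.append((seg_vals, dict(mult)))
    return best_key, best


def random_instance(rng):
    n = int(rng.integers(3, 7))
    cns = [int(rng.integers(1, 4)) for _ in range(n)]
    confident = [bool(rng.random() < 0.7) for _ in range(n)]
    n_free = sum(not c for c in confident)
    while n_free > 2:  # keep the enumeration tractable
        confident[next(i for i, c in enumerate(confident) if not c)] = True
        n_free -= 1
    alternatives = [
        None if c else max(0, cn + (1 if rng.random() < 0.5 else -1))
        for c, cn in zip(confident, cns)
    ]
    n_sv = int(rng.integers(1, 3))
    sv_specs = []
    for _ in range(n_sv):
        su, sv_ = sorted(rng.integers(0, n, size=2))
        sides = [HEAD, TAIL]
        sv_specs.append(
            ((int(su), sides[int(rng.integers(2))]), (int(sv_), sides[int(rng.integers(2))]))
        )
    return make_chain_graph(cns, sv_specs, confident=confident, alternatives=alternatives)


@pytest.mark.parametrize("seed", range(40))
def test_solver_matches_exhaustive_lexicographic_oracle(seed):
    rng = np.random.default_rng(seed)
    g = random_instance(rng)
    max_mult = 4
    key, optima = oracle_optima(g, max_mult)
    assert key is not None, "oracle found no feasible assignment"
    sols = solve_graph(g, max_cn=max_mult)
    imbalance = sum(
        g.balance_residual(n) for n in g.node_edges if n not in g.telomeric
    )
    pos = sum(1 for e in g.sv_edge_list() if e.multiplicity >= 1)
    dev = sum(
        abs(g.segment_edge(Node(s, HEAD)).multiplicity - g.cn[s].integer_cn)
        for s in range(len(g.segments))
        if g.cn.get(s) is not None and not g.cn[s].confident
        and g.cn[s].integer_cn is not None
    )
    assert (imbalance, -pos, dev) == key
    # never prune an SV that every lexicographic optimum keeps positive
    sv_edges = [i for i, e in enumerate(g.edges) if e.kind == "sv"]
    for i in sv_edges:
        if all(mult[i] >= 1 for _, mult in optima):
            assert g.edges[i].multiplicity >= 1


class TestPrune:
    def test_false_positives_removed_true_kept(self):
        g = make_chain_graph(
            [2, 1, 2, 3, 2],
            [((0, TAIL), (2, HEAD)),   # deletion junction (true)
             ((3, HEAD), (3, TAIL)),   # dup junction (true)
             ((0, TAIL), (4, HEAD))],  # spurious on mismatched step
        )
        solve_graph(g)
        retained, removed = prune_zero_multiplicity(g)
        assert len(retained) == 2
        assert len(removed) == 1

    def test_nothing_removed_when_all_positive(self):
        g = make_chain_graph([2, 1, 2], [((0, TAIL), (2, HEAD))])
        solve_graph(g)
        retained, removed = prune_zero_multiplicity(g)
        assert retained and not removed

    def test_unsolved_graph_raises(self):
        g = make_chain_graph([2, 1, 2], [((0, TAIL), (2, HEAD))])
        with pytest.raises(ValueError):
            prune_zero_multiplicity(g)
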