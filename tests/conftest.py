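import numpy as np
import pytest

from karyograph.cnsegment import CNSegment
from karyograph.graph import (
    HEAD,
    REFERENCE,
    SEGMENT,
    SV,
    TAIL,
    BreakpointGraph,
    Edge,
    Node,
    Segment,
)
from karyograph.svcalls import Breakend, SVCall


def make_chain_graph(cns, sv_specs=(), chrom="chr1", seg_len=1000,
                     confident=None, alternatives=None):
    """A single-chromosome chain of segments with given CNs plus SV edges.

    ``sv_specs``: iterable of (node_u, node_v) pairs given as
    (seg, side) tuples. ``confident``: per-segment flags (default all True).
    Segment edges stay unset (the balance program assigns them).
    """
    g = BreakpointGraph()
    n = len(cns)
    for i in range(n):
        g.segments.append(Segment(chrom, i * seg_len + 1, (i + 1) * seg_len))
    for i in range(n):
        g.add_edge(Edge(SEGMENT, Node(i, HEAD), Node(i, TAIL)))
    for i in range(n - 1):
        g.add_edge(Edge(REFERENCE, Node(i, TAIL), Node(i + 1, HEAD)))
    g.telomeric = {Node(0, HEAD), Node(n - 1, TAIL)}
    for (su, sideu), (sv_, sidev) in sv_specs:
        call = SVCall(
            Breakend(chrom, g.segments[su].end if sideu == TAIL else g.segments[su].start, sideu),
            Breakend(chrom, g.segments[sv_].end if sidev == TAIL else g.segments[sv_].start, sidev),
            support_reads=10,
        )
        g.add_edge(Edge(SV, Node(su, sideu), Node(sv_, sidev), sv=call))
    for i, cn in enumerate(cns):
        conf = True if confident is None else confident[i]
        alt = None if alternatives is None else alternatives[i]
        g.cn[i] = CNSegment(
            chrom,
            g.segments[i].start,
            g.segments[i].end,
            copy_ratio=float(cn) if cn is not None else 0.0,
            n_bins=100,
            integer_cn=cn,
            posterior=0.99 if conf else 0.5,
            confident=conf and cn is not None,
            alternative_cn=alt,
            no_depth=cn is None,
        )
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
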