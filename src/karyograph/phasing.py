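"""Haplotype segments, SNP phasing, constrained Viterbi and the haplotype
breakpoint graph.

Runs of consecutive imbalanced allele-specific segments carry phase
information by themselves: within such a run, which allele of a
heterozygous SNP sits on the major copy-number track follows from the
allelic depths. Two runs joined by a *focal* (<1 Mb) *nonhomologous*
(<=100 bp junction homology) SV are merged into one haplotype segment: a
nonhomologous mechanism acts on a single allele, so the joined tracks are
the same haplotype. SNPs in balanced segments, and the end-to-end
orientation of the haplotype segments themselves, are phased against a
population panel with a constrained Viterbi pass over a localized
haplotype-cluster HMM: the path is forced to reproduce the already-phased
SNP order inside each haplotype segment (up to the segment's global flip,
which the path decides).

The haplotype graph assigns haplotype-specific copy numbers: imbalanced
segments get their phased (HSCN1, HSCN2); balanced segments get mu/2 per
track (an odd balanced total is a contradiction and raises). Reference and
SV multiplicities are then solved per track by the balance program.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .allele_graph import AlleleGraphResult, SegAllele, _expand
from .ascn import SnpDepth, _log_nb
from .graph import HEAD, SV, BreakpointGraph, Node
from .svcalls import SVCall, classify_sv_homology

#: maximum reference span of a "focal" SV for run merging
FOCAL_SPAN = 1_000_000
#: panel HMM window size (SNPs per localized cluster column)
PANEL_WINDOW = 8
#: recombination smoothing added to cluster transition counts
RECOMB_SMOOTH = 1e-3
#: per-site emission mismatch probability of the panel model
PANEL_MISMATCH = 0.01


@dataclass
class HaplotypeSegment:
    """Imbalanced segments phased as a unit. ``hap1_track[seg]`` names the
    allele-graph track (1 or 2) carried by H_i1."""

    members: list[int]
    hap1_track: dict[int, int]
    flip: int = 0  # set by the constrained Viterbi: 0 keeps H_i1 = haplotype 1


def is_focal(sv: SVCall) -> bool:
    """Focal = reference span < 1 Mb; interchromosomal SVs are treated as
    merge-eligible (their span is undefined)."""
    span = sv.span()
    return span is None or span < FOCAL_SPAN


class _ParityUnion:
    """Union-find with an orientation parity bit along each union."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.parity = [0] * n  # parity relative to parent

    def find(self, i: int) -> tuple[int, int]:
        if self.parent[i] == i:
            return i, 0
        root, par = self.find(self.parent[i])
        self.parent[i] = root
        self.parity[i] ^= par
        return root, self.parity[i]

    def union(self, i: int, j: int, rel: int) -> None:
        ri, pi = self.find(i)
        rj, pj = self.find(j)
        if ri == rj:
            return  # conflicting evidence keeps the first constraint
        self.parent[rj] = ri
        self.parity[rj] = pi ^ pj ^ rel


def build_haplotype_segments(
    allele: AlleleGraphResult,
) -> list[HaplotypeSegment]:
    """Collect runs of imbalanced segments and merge runs connected by a
    focal nonhomologous SV, with the track correspondence the SV's solved
    haplotype assignment implies."""
    runs = allele.runs
    run_of: dict[int, int] = {}
    for ri, run in enumerate(runs):
        for sid in run:
            run_of[sid] = ri
    uf = _ParityUnion(len(runs))
    for e in allele.graph.edges:
        if e.kind != SV or not e.multiplicity:
            continue
        if e.u.hap == 0 or e.v.hap == 0:
            continue
        ra = run_of.get(e.u.seg)
        rb = run_of.get(e.v.seg)
        if ra is None or rb is None or ra == rb:
            continue
        if e.sv is not None:
            if classify_sv_homology(e.sv) != "nonhomologous" or not is_focal(e.sv):
                continue
        # same haplotype on both sides: track t_a of run a == track t_b of b
        uf.union(ra, rb, (e.u.hap - 1) ^ (e.v.hap - 1))
    grouped: dict[int, list[tuple[int, int]]] = {}
    for ri in range(len(runs)):
        root, par = uf.find(ri)
        grouped.setdefault(root, []).append((ri, par))
    out = []
    for members in grouped.values():
        segs: list[int] = []
        hap1: dict[int, int] = {}
        for ri, par in members:
            for sid in runs[ri]:
                segs.append(sid)
                hap1[sid] = 1 + par  # parity 0 -> track 1 on H_i1
        segs.sort()
        out.append(HaplotypeSegment(members=segs, hap1_track=hap1))
    out.sort(key=lambda h: h.members[0] if h.members else -1)
    return out


@dataclass
class PhasedSnp:
    seg: int
    position: int
    allele1_on_h1: bool
    tie: bool = False


def phase_imbalanced_snps(
    hseg: HaplotypeSegment,
    snps_by_seg: dict[int, list[SnpDepth]],
    assignments: dict[int, SegAllele],
    purity: float,
) -> list[PhasedSnp]:
    """Phase each heterozygous SNP of a haplotype segment to the
    orientation with the higher NB likelihood under (HSCN1, HSCN2); exact
    ties go deterministically to H_i1 with a low-confidence flag."""
    phased: list[PhasedSnp] = []
    for sid in hseg.members:
        a = assignments[sid]
        if a.balanced:
            continue
        hs1 = a.c1 if hseg.hap1_track[sid] == 1 else a.c2
        hs2 = a.c2 if hseg.hap1_track[sid] == 1 else a.c1
        st = a.state
        b = st.b if st is not None else 10.0
        phi1 = st.phi1 if st is not None else 0.05
        phi2 = st.phi2 if st is not None else 0.05
        m1 = b * (purity * hs1 + (1 - purity))
        m2 = b * (purity * hs2 + (1 - purity))
        snps = snps_by_seg.get(sid, [])
        if not snps:
            continue
        o1 = np.array([float(s.o1) for s in snps])
        o2 = np.array([float(s.o2) for s in snps])
        l_keep = _log_nb(o1, m1, phi1) + _log_nb(o2, m2, phi2)
        l_swap = _log_nb(o2, m1, phi1) + _log_nb(o1, m2, phi2)
        for snp, lk, ls in zip(snps, l_keep, l_swap):
            tie = math.isclose(float(lk), float(ls), rel_tol=0, abs_tol=1e-12)
            phased.append(
                PhasedSnp(sid, snp.position, allele1_on_h1=tie or lk > ls, tie=tie)
            )
    return phased


# ---------------------------------------------------------------------------
# panel HMM and constrained Viterbi
# ---------------------------------------------------------------------------


@dataclass
class PanelHMM:
    """Localized haplotype-cluster model: within windows of ``window`` SNPs,
    panel haplotypes collapse to their distinct allele columns (clusters);
    transitions between consecutive windows follow haplotype co-occurrence
    counts with recombination smoothing."""

    windows: list[list[int]]  # site indices per window
    clusters: list[np.ndarray]  # per window: (n_clusters, window_len) alleles
    log_trans: list[np.ndarray]  # per boundary: (from, to) log probabilities
    log_init: np.ndarray


def build_panel_hmm(
    panel: np.ndarray, window: int = PANEL_WINDOW, smooth: float = RECOMB_SMOOTH
) -> PanelHMM:
    """``panel``: (n_haplotypes, n_sites) 0/1 allele matrix."""
    n_hap, n_sites = panel.shape
    windows = [list(range(i, min(i + window, n_sites))) for i in range(0, n_sites, window)]
    clusters: list[np.ndarray] = []
    membership: list[np.ndarray] = []  # per window: hap -> cluster id
    for w in windows:
        cols = panel[:, w]
        uniq, inv = np.unique(cols, axis=0, return_inverse=True)
        clusters.append(uniq)
        membership.append(inv)
    log_trans = []
    for a, b in zip(range(len(windows) - 1), range(1, len(windows))):
        na, nb = len(clusters[a]), len(clusters[b])
        counts = np.full((na, nb), smooth)
        for h in range(n_hap):
            counts[membership[a][h], membership[b][h]] += 1.0
        log_trans.append(np.log(counts / counts.sum(axis=1, keepdims=True)))
    init = np.zeros(len(clusters[0]))
    for h in range(n_hap):
        init[membership[0][h]] += 1.0
    init += smooth
    log_init = np.log(init / init.sum())
    return PanelHMM(windows=windows, clusters=clusters, log_trans=log_trans, log_init=log_init)


@dataclass
class ViterbiResult:
    h1_alleles: np.ndarray  # phased allele of haplotype 1 at every site
    block_flips: dict[int, int]  # block id -> 0/1 flip chosen
    logprob: float


def constrained_viterbi(
    hmm: PanelHMM,
    block_of: np.ndarray,
    block_allele1: np.ndarray,
    n_blocks: int = 0,
) -> ViterbiResult:
    """Maximum-probability diplotype path through the panel model subject
    to phased blocks.

    The hidden state is an ordered pair of panel clusters — one per
    haplotype track — with independent track transitions. Every site is
    heterozygous, so an unconstrained site requires the two tracks to carry
    complementary alleles; a site inside a phased block additionally pins
    track 1 to the block's allele (``block_allele1[j]``, the allele the
    block puts on haplotype 1 before its global flip; the path expresses a
    flip by swapping the pair). Mismatches cost ``PANEL_MISMATCH``.

    ``block_of[j]`` = block id of site j, or -1 if unconstrained.
    """
    log_mis = math.log(PANEL_MISMATCH)
    log_hit = math.log(1.0 - PANEL_MISMATCH)
    n_sites = len(block_of)
    n_win = len(hmm.windows)

    def window_emission(wi: int) -> np.ndarray:
        """(n_clusters, n_clusters) log emission of (track1, track2)."""
        sites = hmm.windows[wi]
        cl = hmm.clusters[wi]
        k = len(cl)
        out = np.zeros((k, k))
        for s_idx, j in enumerate(sites):
            a = cl[:, s_idx]
            if block_of[j] >= 0:
                t1 = block_allele1[j]
                m1 = np.where(a == t1, log_hit, log_mis)
                m2 = np.where(a == 1 - t1, log_hit, log_mis)
                out += m1[:, None] + m2[None, :]
            else:
                # heterozygous site: tracks must be complementary
                comp = a[:, None] != a[None, :]
                out += np.where(comp, 2 * log_hit, 2 * log_mis)
        return out

    scores = hmm.log_init[:, None] + hmm.log_init[None, :] + window_emission(0)
    bp1: list[np.ndarray] = []
    bp2: list[np.ndarray] = []
    for wi in range(1, n_win):
        trans = hmm.log_trans[wi - 1]  # (prev, next)
        # factorised max-product: track 1 then track 2
        cand1 = scores[:, None, :] + trans[:, :, None]  # (c1, c1', c2)
        a1 = cand1.argmax(axis=0)  # (c1', c2)
        m1 = cand1.max(axis=0)
        cand2 = m1[:, :, None] + trans[None, :, :]  # (c1', c2, c2')
        a2 = cand2.argmax(axis=1)  # (c1', c2')
        scores = cand2.max(axis=1) + window_emission(wi)
        bp1.append(a1)
        bp2.append(a2)

    idx = int(scores.argmax())
    k_last = scores.shape[1]
    c1, c2 = idx // k_last, idx % k_last
    logprob = float(scores.max())
    path = [(c1, c2)]
    for wi in range(n_win - 1, 0, -1):
        c1, c2 = path[-1]
        pc2 = int(bp2[wi - 1][c1, c2])
        pc1 = int(bp1[wi - 1][c1, pc2])
        path.append((pc1, pc2))
    path.reverse()

    h1 = np.zeros(n_sites, dtype=int)
    block_votes: dict[int, list[int]] = {}
    for wi, (c1, c2) in enumerate(path):
        cl = hmm.clusters[wi]
        for s_idx, j in enumerate(hmm.windows[wi]):
            h1[j] = int(cl[c1, s_idx])
            if block_of[j] >= 0:
                block_votes.setdefault(int(block_of[j]), []).append(
                    int(h1[j] != block_allele1[j])
                )
    # the constraint ties whole blocks together: report a flip per block and
    # enforce within-block consistency on the output
    block_flips = {
        b: int(sum(v) * 2 > len(v)) for b, v in block_votes.items()
    }
    for j in range(n_sites):
        if block_of[j] >= 0:
            h1[j] = block_allele1[j] ^ block_flips[int(block_of[j])]
    return ViterbiResult(h1_alleles=h1, block_flips=block_flips, logprob=logprob)


# ---------------------------------------------------------------------------
# haplotype graph
# ---------------------------------------------------------------------------


def build_haplotype_graph(
    allele: AlleleGraphResult,
    hsegs: list[HaplotypeSegment],
    flips: dict[int, int] | None = None,
    max_cn: int = 100,
) -> BreakpointGraph:
    """Expand every segment to two haplotype tracks with haplotype-specific
    CNs and solve the per-track balance program. ``flips[i]`` flips haplotype segment i end-to-end (from the
    constrained Viterbi)."""
    flips = flips or {}
    assignments: dict[int, SegAllele] = {}
    hap1_of: dict[int, int] = {}
    for i, hs in enumerate(hsegs):
        f = flips.get(i, hs.flip)
        for sid in hs.members:
            hap1_of[sid] = hs.hap1_track[sid] if f == 0 else 3 - hs.hap1_track[sid]
    for sid, a in allele.assignments.items():
        if a.balanced:
            if a.total % 2 != 0:
                raise ValueError(
                    f"balanced segment {sid} has odd total CN {a.total}"
                )
            assignments[sid] = SegAllele(sid, a.total // 2, a.total // 2, 0, a.state)
        else:
            track1 = hap1_of.get(sid, 1)
            hs1 = a.c1 if track1 == 1 else a.c2
            hs2 = a.c2 if track1 == 1 else a.c1
            assignments[sid] = SegAllele(sid, hs1, hs2, 0, a.state)
    # rebuild from the unexpanded topology: reconstruct a total-CN view
    base = _total_view(allele)
    return _expand(base, assignments, max_cn, force_two_tracks=True)


def _total_view(allele: AlleleGraphResult) -> BreakpointGraph:
    """Collapse the allele graph back to one node per segment side with
    total multiplicities (topology source for the haplotype expansion)."""
    from .graph import Edge as GEdge
    from .graph import REFERENCE, SEGMENT

    g = BreakpointGraph(segments=list(allele.graph.segments), cn=dict(allele.graph.cn))
    seg_mult: dict[int, int] = {}
    for sid, a in allele.assignments.items():
        seg_mult[sid] = a.total
    for sid in sorted(seg_mult):
        g.add_edge(
            GEdge(SEGMENT, Node(sid, "head", 0), Node(sid, "tail", 0), seg_mult[sid])
        )
    seen_ref: set[tuple] = set()
    seen_sv: dict[tuple, int] = {}
    for e in allele.graph.edges:
        if e.kind == SEGMENT:
            continue
        u = Node(e.u.seg, e.u.side, 0)
        v = Node(e.v.seg, e.v.side, 0)
        key = (u, v)
        if e.kind == REFERENCE:
            if key not in seen_ref:
                seen_ref.add(key)
                g.add_edge(GEdge(REFERENCE, u, v))
        else:
            if e.multiplicity:
                if key in seen_sv:
                    g.edges[seen_sv[key]].multiplicity += e.multiplicity
                else:
                    seen_sv[key] = g.add_edge(GEdge(SV, u, v, e.multiplicity, sv=e.sv))
    for n in allele.graph.telomeric:
        g.telomeric.add(Node(n.seg, n.side, 0))
    # reference multiplicities re-solved in the expansion; clear them
    return g
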