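"""Iterative breakpoint-graph refinement.

Each iteration: (1) local BIC segmentation of bin depths pre-divided by the
current SV breakpoints, (2) purity/ploidy fit and integer-CN assignment per
graph segment, (3) balance integer program, (4) pruning of zero-multiplicity
SV edges. Iterations repeat until no SV is pruned (the SV set shrinks
monotonically, so this terminates; a cap of 50 guards pathological cases).

Two rounds are run: the first with a permissive segmentation penalty, then
candidate adjacencies supported by read evidence are imputed between
unbalanced nodes, then a second round with a stricter penalty merges
mis-segmented regions that lack SV evidence. In somatic mode, calls whose
raw evidence also appears in the control are excluded before iterating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .balance import prune_zero_multiplicity, solve_graph
from .cnsegment import (
    BinTable,
    CNSegment,
    PurityPloidyModel,
    assign_integer_cn,
    fit_purity_ploidy,
    local_segment,
)
from .graph import TAIL, BreakpointGraph, Node, build_initial_graph
from .svcalls import HEAD, Breakend, SVCall

#: first/second-round segmentation penalties (simulation profile); a noisy
#: data profile uses 2000 for the second round
LAMBDA_FIRST = 1.0
LAMBDA_SECOND = 16.0
LAMBDA_SECOND_NOISY = 2000.0
ITERATION_CAP = 50


@dataclass
class RefineConfig:
    lam_first: float = LAMBDA_FIRST
    lam_second: float = LAMBDA_SECOND
    max_cn: int = 100
    min_support: int = 3
    window: int = 100
    max_iter: int = ITERATION_CAP
    max_candidates_per_node: int = 20


@dataclass
class IterationLog:
    round: int
    iteration: int
    lam: float
    purity: float
    ploidy: float
    n_svs: int
    n_removed: int
    objective: int


@dataclass
class RefinementResult:
    graph: BreakpointGraph
    model: PurityPloidyModel
    calls: list[SVCall]
    removed: list[SVCall]
    logs: list[IterationLog] = field(default_factory=list)


def sv_cut_positions(calls: list[SVCall]) -> dict[str, set[int]]:
    """'Cut after position' coordinates induced by SV breakends."""
    cuts: dict[str, set[int]] = {}
    for c in calls:
        for bp in (c.bp_a, c.bp_b):
            cut = bp.pos if bp.side == TAIL else bp.pos - 1
            cuts.setdefault(bp.chrom, set()).add(cut)
    return cuts


def cn_breakpoints_from_segments(
    segments: list[CNSegment],
    sv_cuts: dict[str, set[int]],
    bin_size: int,
) -> dict[str, list[int]]:
    """Interior CN segment starts, dropping boundaries that merely echo an
    SV cut within one bin (coincident boundaries deduplicate)."""
    out: dict[str, list[int]] = {}
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start)
        near = sorted(sv_cuts.get(chrom, set()))
        keep = []
        for s in segs[1:]:
            cut = s.start - 1
            i = np.searchsorted(near, cut)
            close = any(
                abs(cut - near[j]) <= bin_size
                for j in (i - 1, i)
                if 0 <= j < len(near)
            )
            if not close:
                keep.append(s.start)
        out[chrom] = keep
    return out


def attach_cn(
    graph: BreakpointGraph,
    bins: BinTable,
    model: PurityPloidyModel,
) -> None:
    """Compute copy ratio and integer CN for every graph segment."""
    expected = bins.expected()
    cum_t: dict[str, np.ndarray] = {}
    cum_e: dict[str, np.ndarray] = {}
    for chrom, t in bins.tumour.items():
        cum_t[chrom] = np.concatenate([[0.0], np.cumsum(t)])
        cum_e[chrom] = np.concatenate([[0.0], np.cumsum(expected[chrom])])
    for sid, seg in enumerate(graph.segments):
        cs = CNSegment(seg.chrom, seg.start, seg.end)
        if seg.virtual or seg.chrom not in cum_t:
            cs.no_depth = True
        else:
            ct, ce = cum_t[seg.chrom], cum_e[seg.chrom]
            lo = max((seg.start - 1) // bins.bin_size, 0)
            hi = min(math.ceil(seg.end / bins.bin_size), len(ct) - 1)
            cs.n_bins = max(hi - lo, 0)
            t_sum = ct[hi] - ct[lo] if hi > lo else 0.0
            e_sum = ce[hi] - ce[lo] if hi > lo else 0.0
            if cs.n_bins == 0 or e_sum <= 0:
                cs.no_depth = True
            else:
                cs.copy_ratio = float(t_sum / e_sum)
                # binomial-scale SE of the mean ratio
                cs.ratio_se = max(
                    math.sqrt(max(t_sum, 1.0)) / e_sum, 5e-3
                )
        assign_integer_cn(cs, model)
        graph.cn[sid] = cs


def attach_baf(
    segments: list[CNSegment],
    snp_depths: dict[str, dict[str, np.ndarray]] | None,
    min_depth: int = 8,
    min_snps: int = 5,
) -> None:
    """Summarise het-SNP allelic balance per segment for the purity fit:
    mean folded BAF deviation, its SE, and the per-SNP binomial noise."""
    if not snp_depths:
        return
    for seg in segments:
        rec = snp_depths.get(seg.chrom)
        if rec is None:
            continue
        pos = rec["positions"]
        lo = np.searchsorted(pos, seg.start, side="left")
        hi = np.searchsorted(pos, seg.end, side="right")
        if hi <= lo:
            continue
        o1 = rec["o1"][lo:hi].astype(float)
        o2 = rec["o2"][lo:hi].astype(float)
        tot = o1 + o2
        keep = tot >= min_depth
        if keep.sum() < min_snps:
            continue
        baf = o1[keep] / tot[keep]
        dev = np.abs(baf - 0.5)
        seg.baf_dev = float(dev.mean())
        seg.baf_dev_se = float(dev.std(ddof=1) / math.sqrt(keep.sum()) + 1e-3)
        seg.baf_noise = float(np.median(0.5 / np.sqrt(tot[keep])))


def exclude_germline(
    calls: list[SVCall],
    germline_evidence: list[SVCall],
    window: int = 100,
) -> tuple[list[SVCall], list[SVCall]]:
    """Split calls into (somatic, germline) by raw evidence in the control
    call set (call-level test)."""
    somatic, germline = [], []
    for c in calls:
        if any(c.is_near(g, window) for g in germline_evidence):
            germline.append(c)
        else:
            somatic.append(c)
    return somatic, germline


def impute_candidate_adjacencies(
    graph: BreakpointGraph,
    unbalanced: list[Node],
    candidate_support: dict[tuple, int],
    min_support: int = 3,
    window: int = 100,
    max_candidates_per_node: int = 20,
) -> list[SVCall]:
    """Add SV edges between unbalanced nodes that read evidence supports.

    ``candidate_support`` maps pairs of breakend keys ((chrom, pos, side),
    (chrom, pos, side)) to supporting read counts (from files or the
    simulator; read remapping itself is not performed here). A candidate is
    accepted if both its breakends fall within ``window`` bp of unbalanced
    nodes of matching side and its support reaches ``min_support``.
    """
    node_coords: list[tuple[str, int, str]] = []
    for n in unbalanced:
        seg = graph.segments[n.seg]
        pos = seg.start if n.side == HEAD else seg.end
        node_coords.append((seg.chrom, pos, n.side))

    def near_unbalanced(key: tuple) -> bool:
        chrom, pos, side = key
        return any(
            c == chrom and s == side and abs(p - pos) <= window
            for c, p, s in node_coords
        )

    new_calls: list[SVCall] = []
    per_node_count: dict[tuple, int] = {}
    for (ka, kb), support in sorted(candidate_support.items()):
        if support < min_support:
            continue
        if not (near_unbalanced(ka) and near_unbalanced(kb)):
            continue
        if per_node_count.get(ka, 0) >= max_candidates_per_node:
            continue
        per_node_count[ka] = per_node_count.get(ka, 0) + 1
        per_node_count[kb] = per_node_count.get(kb, 0) + 1
        new_calls.append(
            SVCall(
                Breakend(*ka),
                Breakend(*kb),
                support_reads=support,
                caller="imputed",
            )
        )
    return new_calls


def _iterate_round(
    calls: list[SVCall],
    bins: BinTable,
    chrom_lengths: dict[str, int],
    lam: float,
    cfg: RefineConfig,
    round_no: int,
    logs: list[IterationLog],
    model: PurityPloidyModel | None,
    snp_depths: dict | None = None,
) -> tuple[BreakpointGraph, PurityPloidyModel, list[SVCall], list[SVCall]]:
    removed_all: list[SVCall] = []
    graph = None
    fit = model
    for it in range(cfg.max_iter):
        sv_cuts = sv_cut_positions(calls)
        predivide = {c: sorted(s) for c, s in sv_cuts.items()}
        cn_segs = local_segment(bins, predivide, lam)
        if model is None and (fit is None or it == 0):
            # the purity fit is refreshed at the start of each round; the
            # grid is the expensive step and segmentations within a round
            # differ only by pruned SV breakpoints
            attach_baf(cn_segs, snp_depths)
            try:
                fit = fit_purity_ploidy(cn_segs, max_cn=cfg.max_cn)
            except ValueError as err:
                # a CN-quiet genome cannot identify purity; proceed with a
                # neutral diploid model rather than refusing the sample
                warnings.warn(f"purity fit failed ({err}); assuming pure diploid",
                              stacklevel=2)
                fit = PurityPloidyModel(p=1.0, tau=2.0, max_cn=cfg.max_cn)
        cn_bps = cn_breakpoints_from_segments(cn_segs, sv_cuts, bins.bin_size)
        graph = build_initial_graph(calls, cn_bps, chrom_lengths)
        attach_cn(graph, bins, fit)
        sols = solve_graph(graph, max_cn=cfg.max_cn)
        retained, removed = prune_zero_multiplicity(graph)
        logs.append(
            IterationLog(
                round=round_no,
                iteration=it + 1,
                lam=lam,
                purity=fit.p,
                ploidy=fit.tau,
                n_svs=len(calls),
                n_removed=len(removed),
                objective=sum(s.objective for s in sols),
            )
        )
        removed_all.extend(removed)
        if not removed:
            return graph, fit, retained, removed_all
        calls = retained
    warnings.warn("iteration cap reached before convergence", stacklevel=2)
    return graph, fit, calls, removed_all


def run_iterations(
    calls: list[SVCall],
    bins: BinTable,
    chrom_lengths: dict[str, int],
    config: RefineConfig | None = None,
    candidate_support: dict[tuple, int] | None = None,
    germline_evidence: list[SVCall] | None = None,
    model: PurityPloidyModel | None = None,
    snp_depths: dict | None = None,
) -> RefinementResult:
    """Two-round iterative refinement with intermediate candidate-adjacency
    imputation. ``model`` fixes purity/ploidy (skips the fit; used on small
    fixtures); ``snp_depths`` feeds allelic balance into the purity fit.
    ``germline_evidence`` switches on somatic mode."""
    cfg = config or RefineConfig()
    logs: list[IterationLog] = []
    removed_all: list[SVCall] = []
    if germline_evidence is not None:
        calls, germ = exclude_germline(calls, germline_evidence, cfg.window)
    graph, fit, calls, removed = _iterate_round(
        calls, bins, chrom_lengths, cfg.lam_first, cfg, 1, logs, model,
        snp_depths,
    )
    removed_all.extend(removed)
    if candidate_support:
        imputed = impute_candidate_adjacencies(
            graph,
            graph.unbalanced_nodes(),
            candidate_support,
            min_support=cfg.min_support,
            window=cfg.window,
            max_candidates_per_node=cfg.max_candidates_per_node,
        )
        if germline_evidence is not None and imputed:
            imputed, _ = exclude_germline(imputed, germline_evidence, cfg.window)
        # an imputed adjacency that duplicates a retained call is dropped
        imputed = [c for c in imputed if not any(c.is_near(r, cfg.window) for r in calls)]
        calls = calls + imputed
    graph, fit, calls, removed = _iterate_round(
        calls, bins, chrom_lengths, cfg.lam_second, cfg, 2, logs,
        model or fit, snp_depths,
    )
    removed_all.extend(removed)
    return RefinementResult(
        graph=graph, model=fit, calls=calls, removed=removed_all, logs=logs
    )
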