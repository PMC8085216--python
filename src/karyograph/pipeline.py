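"""End-to-end orchestration: simulation, refinement, allele-specific CN,
haplotype phasing and evaluation against truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .allele_graph import AlleleGraphResult, build_allele_graph
from .ascn import ASCNSelection, SnpDepth, fit_segment_states, select_ascn
from .cnsegment import BinTable
from .evaluate import PRF, eval_cn, eval_svs, eval_switch_error
from .graph import HEAD, BreakpointGraph, Node
from .phasing import (
    HaplotypeSegment,
    build_haplotype_graph,
    build_haplotype_segments,
    build_panel_hmm,
    constrained_viterbi,
    phase_imbalanced_snps,
)
from .refine import RefineConfig, RefinementResult, run_iterations
from .simulate import (
    GenomeModel,
    SimConfig,
    TruthTables,
    candidate_support_map,
    emit_depth_bins,
    emit_panel,
    emit_snp_depths,
    emulate_callers,
    germline_evidence_calls,
    simulate_genome,
)
from .svcalls import SVCall, filter_low_quality, merge_sv_callsets


@dataclass
class ExperimentResult:
    sv: PRF | None = None
    integer_cn: PRF | None = None
    ascn: PRF | None = None
    ascn_large: PRF | None = None
    switch_error: float | None = None
    purity: float = 0.0
    ploidy: float = 0.0
    n_calls: int = 0
    refinement: RefinementResult | None = None
    allele: AlleleGraphResult | None = None


def snps_by_segment(
    graph: BreakpointGraph, snp_depths: dict[str, dict[str, np.ndarray]]
) -> dict[int, list[SnpDepth]]:
    out: dict[int, list[SnpDepth]] = {}
    for sid, seg in enumerate(graph.segments):
        if seg.virtual or seg.chrom not in snp_depths:
            continue
        rec = snp_depths[seg.chrom]
        pos = rec["positions"]
        lo = np.searchsorted(pos, seg.start, side="left")
        hi = np.searchsorted(pos, seg.end, side="right")
        if hi > lo:
            out[sid] = [
                SnpDepth(int(pos[j]), int(rec["o1"][j]), int(rec["o2"][j]))
                for j in range(lo, hi)
            ]
    return out


def fit_ascn_selections(
    graph: BreakpointGraph,
    seg_snps: dict[int, list[SnpDepth]],
    purity: float,
    max_mu: int = 12,
) -> dict[int, ASCNSelection | None]:
    """NB-EM ASCN selection for every segment of a solved graph."""
    selections: dict[int, ASCNSelection | None] = {}
    for sid, seg in enumerate(graph.segments):
        e = graph.segment_edge(Node(sid, HEAD))
        mu = e.multiplicity if e is not None and e.multiplicity is not None else 0
        snps = seg_snps.get(sid, [])
        usable = [s for s in snps if s.o1 + s.o2 > 0]
        if not usable or mu <= 0 or mu > max_mu:
            selections[sid] = None
            continue
        states = fit_segment_states(mu, usable, purity)
        selections[sid] = select_ascn(states, len(usable))
    return selections


def ascn_segment_table(
    graph: BreakpointGraph, allele: AlleleGraphResult
) -> list[tuple[str, int, int, tuple[int, int]]]:
    out = []
    for sid, seg in enumerate(graph.segments):
        if seg.virtual or seg.length <= 0:
            continue
        a = allele.assignments.get(sid)
        if a is None:
            continue
        pair = tuple(sorted((a.c1, a.c2)))
        out.append((seg.chrom, seg.start, seg.end, pair))
    return out


def cn_segment_table(graph: BreakpointGraph) -> list[tuple[str, int, int, int]]:
    out = []
    for sid, seg in enumerate(graph.segments):
        if seg.virtual or seg.length <= 0:
            continue
        e = graph.segment_edge(Node(sid, HEAD))
        if e is None or e.multiplicity is None:
            continue
        out.append((seg.chrom, seg.start, seg.end, e.multiplicity))
    return out


def truth_ascn_table(truth: TruthTables) -> list[tuple[str, int, int, tuple[int, int]]]:
    out = []
    for chrom, (starts, ends, c1, c2) in truth.cn.items():
        for s, e, a, b in zip(starts, ends, c1, c2):
            out.append((chrom, int(s), int(e), tuple(sorted((int(a), int(b))))))
    return out


def truth_cn_table(truth: TruthTables) -> list[tuple[str, int, int, int]]:
    out = []
    for chrom, (starts, ends, c1, c2) in truth.cn.items():
        for s, e, a, b in zip(starts, ends, c1, c2):
            out.append((chrom, int(s), int(e), int(a + b)))
    return out


def germline_diploid_mask(truth: TruthTables) -> list[tuple[str, int, int]]:
    """Intervals where the control genome is plain diploid (one copy per
    parental haplotype); somatic-mode CN calls are evaluated there, since
    control-normalised ratios do not see germline CN inside germline CNVs."""
    mask = []
    for chrom, (starts, ends, c1, c2) in truth.cn_control.items():
        for s, e, a, b in zip(starts, ends, c1, c2):
            if a == 1 and b == 1:
                mask.append((chrom, int(s), int(e)))
    return mask


def run_phasing(
    allele: AlleleGraphResult,
    snp_depths: dict[str, dict[str, np.ndarray]],
    seg_snps: dict[int, list[SnpDepth]],
    panel: dict[str, np.ndarray],
    purity: float,
) -> tuple[dict[str, np.ndarray], list[HaplotypeSegment]]:
    """Phase every het SNP: imbalanced segments by allelic likelihood within
    haplotype segments, balanced SNPs plus segment orientations by the
    constrained Viterbi over the panel model. Returns per-chromosome h1
    allele vectors (0 = allele1 on haplotype 1)."""
    hsegs = build_haplotype_segments(allele)
    graph = allele.graph
    # site lookup per chromosome
    phased_alleles: dict[str, np.ndarray] = {}
    for chrom, rec in snp_depths.items():
        n = len(rec["positions"])
        block_of = np.full(n, -1, dtype=int)
        block_allele1 = np.zeros(n, dtype=int)
        pos_index = {int(p): j for j, p in enumerate(rec["positions"])}
        for bi, hs in enumerate(hsegs):
            phased = phase_imbalanced_snps(hs, seg_snps, allele.assignments, purity)
            for ps in phased:
                if graph.segments[ps.seg].chrom != chrom:
                    continue
                j = pos_index.get(ps.position)
                if j is None:
                    continue
                block_of[j] = bi
                # allele value 0 codes "allele1"; H_i1 is the candidate h1
                block_allele1[j] = 0 if ps.allele1_on_h1 else 1
        hmm = build_panel_hmm(panel[chrom])
        vit = constrained_viterbi(hmm, block_of, block_allele1, len(hsegs))
        phased_alleles[chrom] = vit.h1_alleles
    return phased_alleles, hsegs


def switch_error_vs_truth(
    phased: dict[str, np.ndarray], truth: TruthTables
) -> float:
    switches = 0
    pairs = 0
    for chrom, h1 in phased.items():
        truth_h1 = (~truth.snps[chrom]["allele1_on_h1"]).astype(int)
        n = len(h1)
        if n < 2:
            continue
        d = h1 ^ truth_h1
        switches += int(np.count_nonzero(np.diff(d)))
        pairs += n - 1
    return switches / pairs if pairs else 0.0


def run_simulated_experiment(
    seed: int,
    somatic: bool = False,
    sim_config: SimConfig | None = None,
    refine_config: RefineConfig | None = None,
    fp_rate: float = 0.3,
    fn_rate: float = 0.1,
    jitter_bp: int = 10,
    n_callers: int = 3,
    with_phasing: bool = False,
    panel_size: int = 20,
    panel_mutation_rate: float = 0.01,
) -> ExperimentResult:
    """One full desk-scale run: simulate, corrupt, refine, estimate ASCN,
    optionally phase; evaluate everything against truth."""
    cfg = sim_config or SimConfig()
    model = simulate_genome(seed, cfg)
    truth = model.truth()
    bins = emit_depth_bins(model, truth, with_control=somatic)
    callsets = emulate_callers(
        truth,
        cfg.chrom_lengths,
        fp_rate=fp_rate,
        fn_rate=fn_rate,
        jitter_bp=jitter_bp,
        n_callers=n_callers,
        seed=seed,
    )
    calls = merge_sv_callsets([filter_low_quality(cs) for cs in callsets])
    germ_ev = germline_evidence_calls(truth, jitter_bp=jitter_bp, seed=seed) if somatic else None
    support = candidate_support_map(truth)
    if somatic:
        support = {
            k: v
            for k, v in support.items()
            if not any(
                t.call.key == (k[0] + k[1]) for t in truth.svs if not t.somatic
            )
        }
    snp_depths = emit_snp_depths(model, truth)
    res = run_iterations(
        calls,
        bins,
        cfg.chrom_lengths,
        config=refine_config,
        candidate_support=support,
        germline_evidence=germ_ev,
        snp_depths=snp_depths,
    )
    out = ExperimentResult(refinement=res, purity=res.model.p, ploidy=res.model.tau)
    out.n_calls = len(res.calls)

    truth_calls = [t.call for t in truth.svs if t.somatic or not somatic]
    out.sv = eval_svs(res.calls, truth_calls)

    mask = germline_diploid_mask(truth) if somatic else None
    out.integer_cn = eval_cn(cn_segment_table(res.graph), truth_cn_table(truth), mask=mask)

    seg_snps = snps_by_segment(res.graph, snp_depths)
    selections = fit_ascn_selections(res.graph, seg_snps, res.model.p)
    allele = build_allele_graph(res.graph, selections)
    out.allele = allele
    called_ascn = ascn_segment_table(res.graph, allele)
    truth_ascn = truth_ascn_table(truth)
    out.ascn = eval_cn(called_ascn, truth_ascn, mask=mask)
    out.ascn_large = eval_cn(called_ascn, truth_ascn, mask=mask, min_length=100_000)

    if with_phasing:
        panel = emit_panel(
            model, truth, n_panel=panel_size, mutation_rate=panel_mutation_rate
        )
        phased, _ = run_phasing(allele, snp_depths, seg_snps, panel, res.model.p)
        out.switch_error = switch_error_vs_truth(phased, truth)
    return out
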