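"""Ground-truthed simulation of rearranged cancer genomes.

A genome model is a set of *molecules*: ordered lists of oriented reference
segments, two parental molecules per chromosome to start. Germline SVs are
applied to the diploid, optional whole-genome doubling copies every
molecule, then somatic SVs rearrange the tumour molecules (deletions,
tandem and inverted duplications, inversions, block-interchange insertions,
reciprocal translocations, fold-backs, chromothripsis, double-minute
excision and breakage-fusion-bridge cycles). Replaying the operations log
reproduces the model exactly; every emitted artefact derives
deterministically from the molecule set:

* truth tables — SV junctions with orientation and multiplicity, per-base
  total/allele-specific CN, segment boundaries, phased het-SNP truth;
* binned read depths — NB counts around coverage x (p * cn_tumour +
  (1-p) * cn_normal) per bin, with a matched control at the germline CN;
* het-SNP allelic depths — NB around b (p * a + (1-p)) per allele track;
* caller-noise-corrupted SV call sets — per-caller false-negative drops,
  false-positive injections and breakpoint jitter, support/mapq drawn so
  that true calls pass the quality filter;
* a phased population panel — the two truth haplotypes plus recombined,
  mutated decoys.

The desk-scale default (2 chromosomes x 50 Mb, ~60 germline + ~20 somatic
SVs) is a 1:50 reduction of a whole-genome scheme of ~3000 germline and
~200 somatic SVs; purity defaults to 0.75 with 60/75/90% available, and
coverage is quoted per haplotype (3-20x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .svcalls import HEAD, TAIL, Breakend, SVCall

DESK_CHROMS = {"chr1": 50_000_000, "chr2": 50_000_000}


class MolSeg(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: int  # +1 / -1
    hap: int  # parental haplotype 1/2

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Molecule:
    segments: list[MolSeg]
    circular: bool = False

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass
class SimConfig:
    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DESK_CHROMS))
    n_germline: int = 60
    n_somatic: int = 20
    wgd: int = 0
    purity: float = 0.75
    coverage: float = 15.0  # per-haplotype fold coverage
    bin_size: int = 100
    read_len: int = 100
    dispersion: float = 0.02  # NB dispersion of bin counts
    snp_dispersion: float = 0.02
    het_density: float = 1.0 / 1500.0
    germline_size_range: tuple[int, int] = (1_000, 100_000)
    somatic_size_range: tuple[int, int] = (10_000, 5_000_000)
    homologous_fraction: float = 0.1
    #: somatic operator mix (uniform by default over the operator set)
    somatic_ops: tuple[str, ...] = (
        "deletion",
        "tandem_dup",
        "inversion",
        "insertion",
        "translocation",
        "foldback",
    )
    germline_ops: tuple[str, ...] = ("deletion", "tandem_dup", "inversion", "insertion")


@dataclass
class TruthSV:
    call: SVCall
    multiplicity: int
    somatic: bool
    haplotype: int


@dataclass
class TruthTables:
    svs: list[TruthSV]
    #: per chromosome: (starts, ends, cn_h1, cn_h2) arrays for the tumour
    cn: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    #: same for the germline (control) genome
    cn_control: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    #: het SNPs: chrom -> (positions, a1 on hap1 flags, tumour a_h1, a_h2)
    snps: dict[str, dict[str, np.ndarray]]

    def cn_at(self, chrom: str, pos: np.ndarray, control: bool = False):
        starts, ends, c1, c2 = (self.cn_control if control else self.cn)[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        idx = np.clip(idx, 0, len(starts) - 1)
        return c1[idx], c2[idx]


@dataclass
class GenomeModel:
    config: SimConfig
    seed: int
    molecules: list[Molecule]
    control_molecules: list[Molecule]
    operations: list[tuple] = field(default_factory=list)

    def truth(self) -> TruthTables:
        return _truth_tables(self)


# ---------------------------------------------------------------------------
# molecule surgery
# ---------------------------------------------------------------------------

def _cut(segs: list[MolSeg], offset: int) -> tuple[list[MolSeg], list[MolSeg]]:
    """Split a segment list so the prefix has ``offset`` bp."""
    if offset <= 0:
        return [], list(segs)
    left: list[MolSeg] = []
    consumed = 0
    for i, s in enumerate(segs):
        if consumed + s.length <= offset:
            left.append(s)
            consumed += s.length
            if consumed == offset:
                return left, list(segs[i + 1:])
            continue
        k = offset - consumed  # bp of this segment in the prefix
        if s.strand > 0:
            a = MolSeg(s.chrom, s.start, s.start + k - 1, s.strand, s.hap)
            b = MolSeg(s.chrom, s.start + k, s.end, s.strand, s.hap)
        else:
            a = MolSeg(s.chrom, s.end - k + 1, s.end, s.strand, s.hap)
            b = MolSeg(s.chrom, s.start, s.end - k, s.strand, s.hap)
        left.append(a)
        return left, [b] + list(segs[i + 1:])
    return left, []


def _reverse(segs: list[MolSeg]) -> list[MolSeg]:
    return [MolSeg(s.chrom, s.start, s.end, -s.strand, s.hap) for s in reversed(segs)]


def _excise(segs, off, size):
    pre, rest = _cut(segs, off)
    mid, post = _cut(rest, size)
    return pre, mid, post


def _apply_op(
    molecules: list[Molecule], op: str, rng: np.random.Generator, size_range
) -> tuple | None:
    linear = [i for i, m in enumerate(molecules) if not m.circular and m.length > 10 * size_range[0]]
    if not linear:
        return None
    weights = np.array([molecules[i].length for i in linear], dtype=float)
    mi = linear[rng.choice(len(linear), p=weights / weights.sum())]
    mol = molecules[mi]
    lo, hi = size_range
    size = int(math.exp(rng.uniform(math.log(lo), math.log(hi))))
    size = min(size, mol.length // 4)
    if size < 50:
        return None
    off = int(rng.integers(1, mol.length - size - 1))
    if op == "deletion":
        pre, _mid, post = _excise(mol.segments, off, size)
        mol.segments = pre + post
    elif op == "tandem_dup":
        pre, mid, post = _excise(mol.segments, off, size)
        mol.segments = pre + mid + mid + post
    elif op == "inversion":
        pre, mid, post = _excise(mol.segments, off, size)
        mol.segments = pre + _reverse(mid) + post
    elif op == "insertion":
        # block interchange: move the block elsewhere in the molecule
        pre, mid, post = _excise(mol.segments, off, size)
        rest = pre + post
        dest = int(rng.integers(0, max(sum(s.length for s in rest) - 1, 1)))
        a, b = _cut(rest, dest)
        mol.segments = a + mid + b
    elif op == "foldback":
        pre, rest = _cut(mol.segments, off)
        dup, _ = _cut(_reverse(pre), size)  # inverted copy of the prefix tail
        mol.segments = pre + dup + rest
    elif op == "translocation":
        others = [i for i in linear if i != mi]
        if not others:
            return None
        mj = others[int(rng.integers(len(others)))]
        other = molecules[mj]
        off2 = int(rng.integers(1, other.length - 1))
        a1, b1 = _cut(mol.segments, off)
        a2, b2 = _cut(other.segments, off2)
        mol.segments = a1 + b2
        other.segments = a2 + b1
    elif op == "chromothripsis":
        pre, mid, post = _excise(mol.segments, off, size)
        n_pieces = int(rng.integers(6, 14))
        cuts = np.sort(rng.choice(np.arange(1, size), size=n_pieces - 1, replace=False))
        pieces = []
        rest = mid
        last = 0
        for c in cuts:
            a, rest = _cut(rest, int(c) - last)
            last = int(c)
            pieces.append(a)
        pieces.append(rest)
        kept = [p for p in pieces if rng.random() < 0.7 and p]
        rng.shuffle(kept)
        out = []
        for p in kept:
            out.extend(_reverse(p) if rng.random() < 0.5 else p)
        mol.segments = pre + out + post
    elif op == "dm_excision":
        pre, mid, post = _excise(mol.segments, off, size)
        mol.segments = pre + post
        copies = int(rng.integers(5, 15))
        for _ in range(copies):
            molecules.append(Molecule(segments=list(mid), circular=True))
    elif op == "bfb":
        cycles = int(rng.integers(2, 4))
        for _ in range(cycles):
            keep = int(rng.integers(mol.length // 2, mol.length - 1))
            pre, _lost = _cut(mol.segments, keep)
            dup_len = min(size, keep - 1)
            dup, _ = _cut(_reverse(pre), dup_len)
            mol.segments = pre + dup
    else:
        raise ValueError(f"unknown operator {op}")
    return (op, mi, off, size)


def simulate_genome(
    seed: int,
    config: SimConfig | None = None,
) -> GenomeModel:
    """Build a rearranged tumour genome with its germline control.

    Operations apply in order germline -> WGD -> somatic; the log records
    every applied operation."""
    cfg = config or SimConfig()
    rng = np.random.default_rng([seed, 1])
    molecules: list[Molecule] = []
    for chrom, length in cfg.chrom_lengths.items():
        for hap in (1, 2):
            molecules.append(Molecule([MolSeg(chrom, 1, length, 1, hap)]))
    ops_log: list[tuple] = []
    applied = 0
    guard = 0
    while applied < cfg.n_germline and guard < cfg.n_germline * 20:
        guard += 1
        op = cfg.germline_ops[int(rng.integers(len(cfg.germline_ops)))]
        rec = _apply_op(molecules, op, rng, cfg.germline_size_range)
        if rec is not None:
            ops_log.append(("germline",) + rec)
            applied += 1
    control = [Molecule(list(m.segments), m.circular) for m in molecules]
    for _ in range(cfg.wgd):
        molecules.extend(Molecule(list(m.segments), m.circular) for m in list(molecules))
        ops_log.append(("wgd",))
    applied = 0
    guard = 0
    while applied < cfg.n_somatic and guard < cfg.n_somatic * 20:
        guard += 1
        op = cfg.somatic_ops[int(rng.integers(len(cfg.somatic_ops)))]
        rec = _apply_op(molecules, op, rng, cfg.somatic_size_range)
        if rec is not None:
            ops_log.append(("somatic",) + rec)
            applied += 1
    return GenomeModel(
        config=cfg, seed=seed, molecules=molecules, control_molecules=control,
        operations=ops_log,
    )


# ---------------------------------------------------------------------------
# truth extraction
# ---------------------------------------------------------------------------

def _junctions(molecules: list[Molecule]) -> dict[tuple, dict]:
    out: dict[tuple, dict] = {}
    for mol in molecules:
        segs = mol.segments
        if not segs:
            continue
        pairs = list(zip(segs, segs[1:]))
        if mol.circular and len(segs) >= 1:
            pairs.append((segs[-1], segs[0]))
        for a, b in pairs:
            if (
                a.chrom == b.chrom
                and a.strand == b.strand
                and (
                    (a.strand > 0 and a.end + 1 == b.start)
                    or (a.strand < 0 and b.end + 1 == a.start)
                )
            ):
                continue  # reference adjacency
            if a.strand > 0:
                bp_a = (a.chrom, a.end, TAIL)
            else:
                bp_a = (a.chrom, a.start, HEAD)
            if b.strand > 0:
                bp_b = (b.chrom, b.start, HEAD)
            else:
                bp_b = (b.chrom, b.end, TAIL)
            key = tuple(sorted([bp_a, bp_b]))
            rec = out.setdefault(key, {"mult": 0, "haps": set()})
            rec["mult"] += 1
            rec["haps"].add(a.hap)
    return out


def _cn_profile(
    molecules: list[Molecule], chrom_lengths: dict[str, int]
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]:
    out = {}
    for chrom, length in chrom_lengths.items():
        events: dict[int, list[int]] = {}
        bounds = {1, length + 1}
        for mol in molecules:
            for s in mol.segments:
                if s.chrom != chrom:
                    continue
                bounds.add(s.start)
                bounds.add(s.end + 1)
        pos = np.array(sorted(bounds))
        starts = pos[:-1]
        ends = pos[1:] - 1
        c1 = np.zeros(len(starts), dtype=int)
        c2 = np.zeros(len(starts), dtype=int)
        for mol in molecules:
            for s in mol.segments:
                if s.chrom != chrom:
                    continue
                i = np.searchsorted(starts, s.start)
                j = np.searchsorted(starts, s.end + 1)
                (c1 if s.hap == 1 else c2)[i:j] += 1
        out[chrom] = (starts, ends, c1, c2)
    return out


def _truth_tables(model: GenomeModel) -> TruthTables:
    cfg = model.config
    rng = np.random.default_rng([model.seed, 2])
    tumour_j = _junctions(model.molecules)
    control_j = _junctions(model.control_molecules)
    svs: list[TruthSV] = []
    for key in sorted(tumour_j):
        rec = tumour_j[key]
        somatic = key not in control_j
        if rng.random() < cfg.homologous_fraction:
            hom = int(rng.integers(101, 300))
        else:
            hom = int(rng.integers(0, 21))
        call = SVCall(
            Breakend(*key[0]),
            Breakend(*key[1]),
            support_reads=max(3, int(rec["mult"] * cfg.coverage / 2)),
            mapq=60,
            homology_len=hom,
            somatic=somatic,
        )
        svs.append(
            TruthSV(
                call=call,
                multiplicity=rec["mult"],
                somatic=somatic,
                haplotype=min(rec["haps"]),
            )
        )
    cn = _cn_profile(model.molecules, cfg.chrom_lengths)
    cn_control = _cn_profile(model.control_molecules, cfg.chrom_lengths)

    # het SNP truth
    snps: dict[str, dict[str, np.ndarray]] = {}
    rng_snp = np.random.default_rng([model.seed, 3])
    for chrom, length in cfg.chrom_lengths.items():
        n = rng_snp.poisson(length * cfg.het_density)
        positions = np.sort(rng_snp.choice(np.arange(1, length + 1), size=n, replace=False))
        allele1_on_h1 = rng_snp.integers(0, 2, size=n).astype(bool)
        starts, ends, c1, c2 = cn[chrom]
        idx = np.clip(np.searchsorted(starts, positions, side="right") - 1, 0, len(starts) - 1)
        snps[chrom] = {
            "positions": positions,
            "allele1_on_h1": allele1_on_h1,
            "a_h1": c1[idx],
            "a_h2": c2[idx],
        }
    return TruthTables(svs=svs, cn=cn, cn_control=cn_control, snps=snps)


# ---------------------------------------------------------------------------
# emitters
# ---------------------------------------------------------------------------

def _binned_cn(
    profile, chrom: str, n_bins: int, bin_size: int
) -> np.ndarray:
    """Average total CN per bin from a (starts, ends, c1, c2) profile."""
    starts, ends, c1, c2 = profile[chrom]
    total = (c1 + c2).astype(float)
    out = np.zeros(n_bins)
    for s, e, c in zip(starts, ends, total):
        if c == 0:
            continue
        b0 = (s - 1) // bin_size
        b1 = min((e - 1) // bin_size, n_bins - 1)
        if b0 == b1:
            out[b0] += c * (e - s + 1) / bin_size
            continue
        # partial first/last bins, full bins between
        out[b0] += c * ((b0 + 1) * bin_size - (s - 1)) / bin_size
        out[b1] += c * ((e) - b1 * bin_size) / bin_size
        if b1 - b0 > 1:
            out[b0 + 1:b1] += c
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    if phi <= 1e-9:
        return rng.poisson(mean)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def emit_depth_bins(
    model: GenomeModel,
    truth: TruthTables | None = None,
    coverage: float | None = None,
    purity: float | None = None,
    with_control: bool = True,
    seed_offset: int = 4,
):
    """NB-distributed tumour (and matched control) bin counts.

    Expected tumour count per bin: coverage * (bin/read length) *
    (p * cn_tumour + (1-p) * cn_normal); the control is drawn at the
    germline CN."""
    from .cnsegment import BinTable

    cfg = model.config
    truth = truth or model.truth()
    coverage = coverage if coverage is not None else cfg.coverage
    purity = purity if purity is not None else cfg.purity
    rng = np.random.default_rng([model.seed, seed_offset])
    scale = coverage * cfg.bin_size / cfg.read_len  # reads per bin per haploid copy
    table = BinTable(bin_size=cfg.bin_size, tumour={}, control={} if with_control else None)
    for chrom, length in cfg.chrom_lengths.items():
        n_bins = length // cfg.bin_size
        cn_t = _binned_cn(truth.cn, chrom, n_bins, cfg.bin_size)
        cn_n = _binned_cn(truth.cn_control, chrom, n_bins, cfg.bin_size)
        mean_t = scale * (purity * cn_t + (1 - purity) * cn_n)
        table.tumour[chrom] = _nb_draw(rng, mean_t, cfg.dispersion)
        if with_control:
            table.control[chrom] = _nb_draw(rng, scale * cn_n, cfg.dispersion)
    return table


def emit_snp_depths(
    model: GenomeModel,
    truth: TruthTables | None = None,
    coverage: float | None = None,
    purity: float | None = None,
    seed_offset: int = 5,
) -> dict[str, dict[str, np.ndarray]]:
    """Allelic depths of het SNPs: NB around b (p a + (1-p)) per allele,
    b = per-haplotype base coverage."""
    cfg = model.config
    truth = truth or model.truth()
    b = coverage if coverage is not None else cfg.coverage
    p = purity if purity is not None else cfg.purity
    rng = np.random.default_rng([model.seed, seed_offset])
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, rec in truth.snps.items():
        a_h1 = rec["a_h1"].astype(float)
        a_h2 = rec["a_h2"].astype(float)
        d_h1 = _nb_draw(rng, b * (p * a_h1 + (1 - p)), cfg.snp_dispersion)
        d_h2 = _nb_draw(rng, b * (p * a_h2 + (1 - p)), cfg.snp_dispersion)
        on1 = rec["allele1_on_h1"]
        o1 = np.where(on1, d_h1, d_h2)
        o2 = np.where(on1, d_h2, d_h1)
        out[chrom] = {
            "positions": rec["positions"],
            "o1": o1,
            "o2": o2,
        }
    return out


def emulate_callers(
    truth: TruthTables,
    chrom_lengths: dict[str, int],
    fp_rate: float = 0.3,
    fn_rate: float = 0.1,
    jitter_bp: int = 10,
    n_callers: int = 3,
    seed: int = 0,
    somatic_only: bool = False,
) -> list[list[SVCall]]:
    """Noise-corrupted per-caller SV call sets: each caller independently
    drops true SVs, adds random false positives and jitters breakpoints;
    support and mapq are drawn so that true calls pass the quality filter."""
    rng = np.random.default_rng([seed, 6])
    chroms = sorted(chrom_lengths)
    callsets: list[list[SVCall]] = []
    source = [t for t in truth.svs if (t.somatic or not somatic_only)]
    for ci in range(n_callers):
        calls: list[SVCall] = []
        for t in source:
            if rng.random() < fn_rate:
                continue
            bps = []
            for bp in (t.call.bp_a, t.call.bp_b):
                j = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
                pos = min(max(bp.pos + j, 1), chrom_lengths[bp.chrom])
                bps.append(Breakend(bp.chrom, pos, bp.side))
            calls.append(
                SVCall(
                    bps[0],
                    bps[1],
                    support_reads=int(rng.integers(5, 40)),
                    mapq=60,
                    homology_len=t.call.homology_len,
                    caller=f"caller{ci}",
                )
            )
        n_fp = int(round(fp_rate * len(source)))
        for _ in range(n_fp):
            ca, cb = (chroms[int(rng.integers(len(chroms)))] for _ in range(2))
            pa = int(rng.integers(1000, chrom_lengths[ca] - 1000))
            pb = int(rng.integers(1000, chrom_lengths[cb] - 1000))
            sa = HEAD if rng.random() < 0.5 else TAIL
            sb = HEAD if rng.random() < 0.5 else TAIL
            if ca == cb and abs(pa - pb) < 1000:
                continue
            calls.append(
                SVCall(
                    Breakend(ca, pa, sa),
                    Breakend(cb, pb, sb),
                    support_reads=int(rng.integers(3, 15)),
                    mapq=int(rng.integers(20, 61)),
                    homology_len=0,
                    caller=f"caller{ci}",
                )
            )
        callsets.append(calls)
    return callsets


def germline_evidence_calls(truth: TruthTables, jitter_bp: int = 10, seed: int = 0) -> list[SVCall]:
    """Control-sample SV evidence: the germline truth junctions (jittered),
    used by somatic mode to exclude germline calls."""
    rng = np.random.default_rng([seed, 7])
    out = []
    for t in truth.svs:
        if t.somatic:
            continue
        bps = []
        for bp in (t.call.bp_a, t.call.bp_b):
            j = int(rng.integers(-jitter_bp, jitter_bp + 1)) if jitter_bp else 0
            bps.append(Breakend(bp.chrom, max(bp.pos + j, 1), bp.side))
        out.append(SVCall(bps[0], bps[1], support_reads=10, mapq=60,
                          homology_len=t.call.homology_len))
    return out


def candidate_support_map(truth: TruthTables, support: int = 5) -> dict[tuple, int]:
    """Read support for candidate adjacencies at true junctions (stands in
    for remapping discordant/unmapped reads to candidate adjacencies)."""
    out = {}
    for t in truth.svs:
        ka = (t.call.bp_a.chrom, t.call.bp_a.pos, t.call.bp_a.side)
        kb = (t.call.bp_b.chrom, t.call.bp_b.pos, t.call.bp_b.side)
        out[(ka, kb)] = max(support, t.multiplicity * 2)
    return out


def emit_panel(
    model: GenomeModel,
    truth: TruthTables | None = None,
    n_panel: int = 20,
    mutation_rate: float = 0.01,
    switch_rate: float = 0.05,
    seed_offset: int = 8,
) -> dict[str, np.ndarray]:
    """Phased population panel per chromosome: (n_panel, n_sites) 0/1
    matrix whose first two rows are the truth haplotypes; the rest are
    recombined (switch_rate per site) and mutated (mutation_rate) decoys."""
    if n_panel < 2:
        raise ValueError("panel needs >= 2 haplotypes")
    truth = truth or model.truth()
    rng = np.random.default_rng([model.seed, seed_offset])
    out = {}
    for chrom, rec in truth.snps.items():
        # h1 allele coding: 0 if allele1 is on haplotype 1
        h1 = (~rec["allele1_on_h1"]).astype(int)
        h2 = 1 - h1
        n = len(h1)
        rows = [h1, h2]
        for _ in range(n_panel - 2):
            switches = rng.random(n) < switch_rate
            track = np.cumsum(switches) % 2
            base = np.where(track == 0, h1, h2)
            mut = rng.random(n) < mutation_rate
            rows.append(np.where(mut, 1 - base, base))
        out[chrom] = np.array(rows, dtype=int)
    return out
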