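"""File formats: SV calls (VCF breakend pairs / symbolic ALTs, BEDPE),
depth bins (BED-like TSV), het-SNP allelic depths (VCF with AD), phased
panels (TSV), and TSV serialisation of graphs, CN segments and karyotypes.

Coordinates are 1-based inclusive in memory; BEDPE and BED convert to and
from 0-based half-open at this boundary.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .cnsegment import BinTable, CNSegment
from .graph import BreakpointGraph, Node
from .svcalls import HEAD, TAIL, Breakend, SVCall

# ---------------------------------------------------------------------------
# SV calls
# ---------------------------------------------------------------------------

_BND_RE = re.compile(r"([\[\]])([^:\[\]]+):(\d+)([\[\]])")

_SYMBOLIC_ORIENT = {"DEL": ("tail", "head"), "DUP": ("head", "tail"), "INV": None}


def read_bedpe(path: str | Path) -> list[SVCall]:
    """BEDPE: chrom1 start1 end1 chrom2 start2 end2 name score strand1
    strand2 [support mapq homlen]. Breakend position = end of the 0-based
    half-open interval; strand +/- maps to tail/head attachment."""
    calls = []
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    for row in df.itertuples(index=False):
        r = list(row)
        side1 = TAIL if r[8] == "+" else HEAD
        side2 = TAIL if r[9] == "+" else HEAD
        pos1 = int(r[2]) if side1 == TAIL else int(r[1]) + 1
        pos2 = int(r[5]) if side2 == TAIL else int(r[4]) + 1
        support = int(r[10]) if len(r) > 10 else 0
        mapq = float(r[11]) if len(r) > 11 else 60.0
        hom = int(r[12]) if len(r) > 12 else None
        calls.append(
            SVCall(
                Breakend(str(r[0]), pos1, side1),
                Breakend(str(r[3]), pos2, side2),
                support_reads=support,
                mapq=mapq,
                homology_len=hom,
            )
        )
    return calls


def write_bedpe(calls: list[SVCall], path: str | Path) -> None:
    rows = []
    for c in calls:
        fields = []
        for bp in (c.bp_a, c.bp_b):
            if bp.side == TAIL:
                start, end, strand = bp.pos - 1, bp.pos, "+"
            else:
                start, end, strand = bp.pos - 1, bp.pos, "-"
            fields.append((bp.chrom, start, end, strand))
        (c1, s1, e1, st1), (c2, s2, e2, st2) = fields
        rows.append(
            [c1, s1, e1, c2, s2, e2, "sv", c.support_reads, st1, st2,
             c.support_reads, c.mapq, c.homology_len if c.homology_len is not None else "."]
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _parse_bnd_alt(alt: str):
    m = _BND_RE.search(alt)
    if not m:
        return None
    b1, chrom, pos, b2 = m.groups()
    # t[p[ / t]p] : piece extending right/left of the mate
    mate_side = HEAD if b1 == "[" or b2 == "[" else TAIL
    # REF before brackets -> this breakend keeps its left side (tail)
    this_side = TAIL if not alt.startswith(("[", "]")) else HEAD
    return chrom, int(pos), mate_side, this_side


def read_sv_vcf(path: str | Path) -> list[SVCall]:
    """SV VCF supporting breakend (BND) pairs and symbolic <DEL>/<DUP>/<INV>
    ALTs. INFO keys used: SVTYPE, END, SR (support), HOMLEN; MATEID pairs
    BND records (each pair emitted once)."""
    calls: list[SVCall] = []
    seen_mates: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos, vid, _ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            qual = float(f[5]) if f[5] not in (".", "") else 60.0
            info = dict(
                kv.split("=", 1) if "=" in kv else (kv, True)
                for kv in f[7].split(";")
                if kv
            )
            support = int(info.get("SR", 0))
            hom = int(info["HOMLEN"]) if "HOMLEN" in info else None
            svtype = info.get("SVTYPE", "")
            if svtype == "BND" or _BND_RE.search(alt):
                if vid in seen_mates:
                    continue
                mate = info.get("MATEID")
                if mate:
                    seen_mates.add(mate)
                parsed = _parse_bnd_alt(alt)
                if parsed is None:
                    continue
                mchrom, mpos, mate_side, this_side = parsed
                calls.append(
                    SVCall(
                        Breakend(chrom, pos, this_side),
                        Breakend(mchrom, mpos, mate_side),
                        support_reads=support,
                        mapq=qual,
                        homology_len=hom,
                    )
                )
            elif svtype in ("DEL", "DUP", "INV") or alt in ("<DEL>", "<DUP>", "<INV>"):
                svtype = svtype or alt.strip("<>")
                end = int(info["END"])
                if svtype == "DEL":
                    a, b = Breakend(chrom, pos, TAIL), Breakend(chrom, end, HEAD)
                    calls.append(SVCall(a, b, support_reads=support, mapq=qual, homology_len=hom))
                elif svtype == "DUP":
                    a, b = Breakend(chrom, pos, HEAD), Breakend(chrom, end, TAIL)
                    calls.append(SVCall(a, b, support_reads=support, mapq=qual, homology_len=hom))
                else:  # INV: two junctions
                    calls.append(
                        SVCall(
                            Breakend(chrom, pos - 1, TAIL),
                            Breakend(chrom, end, TAIL),
                            support_reads=support, mapq=qual, homology_len=hom,
                        )
                    )
                    calls.append(
                        SVCall(
                            Breakend(chrom, pos, HEAD),
                            Breakend(chrom, end + 1, HEAD),
                            support_reads=support, mapq=qual, homology_len=hom,
                        )
                    )
    return calls


def write_sv_vcf(calls: list[SVCall], path: str | Path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write calls as BND pairs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">\n')
        fh.write('##INFO=<ID=SR,Number=1,Type=Integer,Description="Supporting reads">\n')
        fh.write('##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Junction homology length">\n')
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls):
            ids = (f"bnd_{i}_a", f"bnd_{i}_b")
            for k, (bp, mate) in enumerate(((c.bp_a, c.bp_b), (c.bp_b, c.bp_a))):
                bracket = "[" if mate.side == HEAD else "]"
                mate_ref = f"{bracket}{mate.chrom}:{mate.pos}{bracket}"
                alt = f"N{mate_ref}" if bp.side == TAIL else f"{mate_ref}N"
                hom = f";HOMLEN={c.homology_len}" if c.homology_len is not None else ""
                fh.write(
                    f"{bp.chrom}\t{bp.pos}\t{ids[k]}\tN\t{alt}\t{c.mapq:.0f}\t"
                    f"PASS\tSVTYPE=BND;MATEID={ids[1-k]};SR={c.support_reads}{hom}\n"
                )


# ---------------------------------------------------------------------------
# bins, SNPs, panels
# ---------------------------------------------------------------------------

def read_bins(path: str | Path, bin_size: int = 100) -> BinTable:
    """BED-like TSV: chrom, start (0-based), end, tumour_count[,
    control_count]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    has_control = df.shape[1] >= 5
    table = BinTable(bin_size=bin_size, tumour={}, control={} if has_control else None)
    for chrom, sub in df.groupby(0, sort=False):
        sub = sub.sort_values(1)
        table.tumour[str(chrom)] = sub[3].to_numpy(dtype=float)
        if has_control:
            table.control[str(chrom)] = sub[4].to_numpy(dtype=float)
    return table


def write_bins(table: BinTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in table.chroms():
            t = table.tumour[chrom]
            c = table.control[chrom] if table.has_control else None
            for i, v in enumerate(t):
                row = f"{chrom}\t{i * table.bin_size}\t{(i + 1) * table.bin_size}\t{int(v)}"
                if c is not None:
                    row += f"\t{int(c[i])}"
                fh.write(row + "\n")


def read_snp_vcf(path: str | Path) -> dict[str, dict[str, np.ndarray]]:
    """Het-SNP VCF with an AD-style FORMAT field; returns per-chromosome
    positions and allelic depths (o1 = REF-supporting, o2 = ALT)."""
    rows: dict[str, list[tuple[int, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, pos = f[0], int(f[1])
            fmt = f[8].split(":")
            sample = f[9].split(":")
            ad = sample[fmt.index("AD")]
            o1, o2 = (int(x) for x in ad.split(",")[:2])
            rows.setdefault(chrom, []).append((pos, o1, o2))
    out = {}
    for chrom, items in rows.items():
        items.sort()
        arr = np.array(items)
        out[chrom] = {
            "positions": arr[:, 0],
            "o1": arr[:, 1],
            "o2": arr[:, 2],
        }
    return out


def write_snp_vcf(snps: dict[str, dict[str, np.ndarray]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for chrom, rec in snps.items():
            for pos, o1, o2 in zip(rec["positions"], rec["o1"], rec["o2"]):
                fh.write(
                    f"{chrom}\t{int(pos)}\t.\tA\tC\t.\tPASS\t.\tGT:AD\t0/1:{int(o1)},{int(o2)}\n"
                )


def read_panel(path: str | Path) -> dict[str, np.ndarray]:
    """Phased-panel TSV: chrom, pos, then one 0/1 allele column per panel
    haplotype; returns (n_haplotypes, n_sites) per chromosome."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    hap_cols = [c for c in df.columns if c.startswith("hap")]
    for chrom, sub in df.groupby(df.columns[0], sort=False):
        sub = sub.sort_values(df.columns[1])
        out[str(chrom)] = sub[hap_cols].to_numpy(dtype=int).T
    return out


def write_panel(panel: dict[str, np.ndarray], positions: dict[str, np.ndarray], path: str | Path) -> None:
    frames = []
    for chrom, mat in panel.items():
        df = pd.DataFrame(mat.T, columns=[f"hap{i}" for i in range(mat.shape[0])])
        df.insert(0, "pos", positions[chrom])
        df.insert(0, "chrom", chrom)
        frames.append(df)
    pd.concat(frames).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# graph / segment tables
# ---------------------------------------------------------------------------

def write_graph(graph: BreakpointGraph, prefix: str | Path) -> None:
    """Two TSVs: <prefix>.segments.tsv (chrom, start, end, virtual, cn) and
    <prefix>.edges.tsv (kind, endpoints, multiplicity)."""
    prefix = str(prefix)
    with open(prefix + ".segments.tsv", "w") as fh:
        fh.write("seg\tchrom\tstart\tend\tvirtual\tcn\n")
        for sid, seg in enumerate(graph.segments):
            e = graph.segment_edge(Node(sid, HEAD)) or graph.segment_edge(Node(sid, HEAD, 1))
            cn = e.multiplicity if e is not None and e.multiplicity is not None else "."
            fh.write(f"{sid}\t{seg.chrom}\t{seg.start}\t{seg.end}\t{int(seg.virtual)}\t{cn}\n")
    with open(prefix + ".edges.tsv", "w") as fh:
        fh.write("kind\tseg_u\tside_u\thap_u\tseg_v\tside_v\thap_v\tmultiplicity\n")
        for e in graph.edges:
            mult = e.multiplicity if e.multiplicity is not None else "."
            fh.write(
                f"{e.kind}\t{e.u.seg}\t{e.u.side}\t{e.u.hap}\t"
                f"{e.v.seg}\t{e.v.side}\t{e.v.hap}\t{mult}\n"
            )


def read_graph(prefix: str | Path) -> BreakpointGraph:
    from .graph import Edge, Segment

    prefix = str(prefix)
    g = BreakpointGraph()
    segs = pd.read_csv(prefix + ".segments.tsv", sep="\t")
    for row in segs.itertuples(index=False):
        g.segments.append(
            Segment(str(row.chrom), int(row.start), int(row.end), bool(row.virtual))
        )
    edges = pd.read_csv(prefix + ".edges.tsv", sep="\t")
    for row in edges.itertuples(index=False):
        mult = None if str(row.multiplicity) == "." else int(row.multiplicity)
        g.add_edge(
            Edge(
                str(row.kind),
                Node(int(row.seg_u), str(row.side_u), int(row.hap_u)),
                Node(int(row.seg_v), str(row.side_v), int(row.hap_v)),
                mult,
            )
        )
    # telomeres: chromosome-extreme segment ends
    by_chrom: dict[str, list[int]] = {}
    for sid, seg in enumerate(g.segments):
        by_chrom.setdefault(seg.chrom, []).append(sid)
    for sids in by_chrom.values():
        for hap in (0, 1, 2):
            if Node(sids[0], HEAD, hap) in g.node_edges:
                g.telomeric.add(Node(sids[0], HEAD, hap))
            if Node(sids[-1], TAIL, hap) in g.node_edges:
                g.telomeric.add(Node(sids[-1], TAIL, hap))
    return g


def write_segments_tsv(segments: list[CNSegment], path: str | Path) -> None:
    """SEG-style table of CN segments."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tn_bins\tcopy_ratio\tinteger_cn\tposterior\tconfident\n")
        for s in segments:
            cn = s.integer_cn if s.integer_cn is not None else "."
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.n_bins}\t{s.copy_ratio:.4f}\t"
                f"{cn}\t{s.posterior:.4f}\t{int(s.confident)}\n"
            )
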