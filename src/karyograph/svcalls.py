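"""Structural-variant call model, quality filtering and call-set merging.

A structural variant (SV) is a novel adjacency between two breakends. Each
breakend attaches to one side of a genomic segment: the *head* is the 5'
coordinate of the segment in the reference, the *tail* the 3' coordinate.
Sorting the two breakends by (chromosome, position) and reading off the
attachment sides gives the orientation class HH, HT, TH or TT:

========================  ===========
adjacency type            orientation
========================  ===========
deletion-type             TH
tandem-duplication-type   HT
inversion-type            HH or TT
========================  ===========

(tail of the left segment joined to head of the right segment is what a
simple deletion produces, hence deletion = TH; the same table is used by the
simulator and the file readers, so the convention is defined exactly once.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

HEAD = "head"
TAIL = "tail"

#: default window (bp) within which two breakpoints count as the same SV
MERGE_WINDOW = 100
#: quality-filter defaults: minimum supporting reads and mapping quality
MIN_SUPPORT = 3
MIN_MAPQ = 20
#: homology length (bp) above which an SV counts as homologous
HOMOLOGY_THRESHOLD = 100


@dataclass(frozen=True, order=True)
class Breakend:
    """One end of a novel adjacency: a 1-based coordinate plus the side of
    the genomic segment it attaches to."""

    chrom: str
    pos: int
    side: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"breakend position must be >= 1, got {self.pos}")
        if self.side not in (HEAD, TAIL):
            raise ValueError(f"side must be 'head' or 'tail', got {self.side!r}")


def _chrom_key(chrom: str):
    body = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


@dataclass
class SVCall:
    """A paired-breakend SV call with its supporting evidence.

    Breakends are stored in canonical order (sorted by chromosome then
    coordinate); the constructor swaps them if needed. ``orientation`` is
    derived from the breakend sides and kept consistent with them.
    """

    bp_a: Breakend
    bp_b: Breakend
    support_reads: int = 0
    mapq: float = 60.0
    homology_len: int | None = None
    somatic: bool = False
    source_sample: str | None = None
    caller: str | None = None
    sample_evidence: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.support_reads < 0:
            raise ValueError("support_reads must be >= 0")
        ka = (_chrom_key(self.bp_a.chrom), self.bp_a.pos, self.bp_a.side)
        kb = (_chrom_key(self.bp_b.chrom), self.bp_b.pos, self.bp_b.side)
        if kb < ka:
            self.bp_a, self.bp_b = self.bp_b, self.bp_a

    @property
    def orientation(self) -> str:
        return self.bp_a.side[0].upper() + self.bp_b.side[0].upper()

    @property
    def key(self) -> tuple:
        return (
            self.bp_a.chrom,
            self.bp_a.pos,
            self.bp_a.side,
            self.bp_b.chrom,
            self.bp_b.pos,
            self.bp_b.side,
        )

    def span(self) -> int | None:
        """Reference distance between breakends; None if interchromosomal."""
        if self.bp_a.chrom != self.bp_b.chrom:
            return None
        return abs(self.bp_b.pos - self.bp_a.pos)

    def is_near(self, other: "SVCall", window: int = MERGE_WINDOW) -> bool:
        """True if both breakpoints overlap within ``window`` bp and the
        orientations agree."""
        return (
            self.orientation == other.orientation
            and self.bp_a.chrom == other.bp_a.chrom
            and self.bp_b.chrom == other.bp_b.chrom
            and abs(self.bp_a.pos - other.bp_a.pos) < window
            and abs(self.bp_b.pos - other.bp_b.pos) < window
        )


def filter_low_quality(
    calls: list[SVCall],
    min_support: int = MIN_SUPPORT,
    min_mapq: float = MIN_MAPQ,
) -> list[SVCall]:
    """Drop low-quality SVs: fewer than ``min_support`` supporting reads or
    mapping quality below ``min_mapq`` (inclusive thresholds retain)."""
    if min_support < 0 or min_mapq < 0:
        raise ValueError("quality thresholds must be >= 0")
    return [c for c in calls if c.support_reads >= min_support and c.mapq >= min_mapq]


def _namespace(chrom: str) -> str:
    return "chr" if chrom.startswith("chr") else "plain"


def _check_namespaces(callsets: list[list[SVCall]]) -> None:
    spaces = {
        _namespace(c.bp_a.chrom) for cs in callsets for c in cs
    } | {_namespace(c.bp_b.chrom) for cs in callsets for c in cs}
    if len(spaces) > 1:
        raise ValueError(
            "callsets use different chromosome namespaces (chr-prefixed and plain)"
        )


def _cluster(calls: list[tuple[int, int, SVCall]], window: int) -> list[list[tuple[int, int, SVCall]]]:
    """Single-linkage clustering of same-orientation calls under the
    <window-bp double-breakpoint overlap rule."""
    n = len(calls)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: calls[i][2].bp_a.pos)
    for ii in range(n):
        i = order[ii]
        for jj in range(ii + 1, n):
            j = order[jj]
            if calls[j][2].bp_a.pos - calls[i][2].bp_a.pos >= window:
                break
            if calls[i][2].is_near(calls[j][2], window):
                parent[find(i)] = find(j)
    groups: dict[int, list[tuple[int, int, SVCall]]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(calls[i])
    return list(groups.values())


def merge_sv_callsets(
    callsets: list[list[SVCall]],
    window: int = MERGE_WINDOW,
) -> list[SVCall]:
    """Union multiple SV call sets, collapsing duplicates.

    Breakpoints overlapping within ``window`` bp (strict) with the same
    orientation are one SV. The representative breakpoints come from the
    member with the highest support; ties go to the earliest callset in the
    given priority order. Orientation disagreement within a cluster splits
    the cluster (clustering is per orientation class).
    """
    if window <= 0:
        raise ValueError("merge window must be > 0")
    _check_namespaces(callsets)
    buckets: dict[tuple, list[tuple[int, int, SVCall]]] = {}
    for prio, cs in enumerate(callsets):
        for idx, call in enumerate(cs):
            bucket = (call.bp_a.chrom, call.bp_b.chrom, call.orientation)
            buckets.setdefault(bucket, []).append((prio, idx, call))
    merged: list[SVCall] = []
    for bucket_calls in buckets.values():
        for group in _cluster(bucket_calls, window):
            prio, _, rep = min(group, key=lambda t: (-t[2].support_reads, t[0], t[1]))
            evidence: dict[str, bool] = {}
            for _, _, c in group:
                for s, v in c.sample_evidence.items():
                    evidence[s] = evidence.get(s, False) or v
                if c.source_sample is not None:
                    evidence[c.source_sample] = True
            merged.append(replace(rep, sample_evidence=evidence))
    merged.sort(key=lambda c: c.key)
    return merged


def unify_multisample(
    calls_by_sample: dict[str, list[SVCall]],
    window: int = MERGE_WINDOW,
) -> list[SVCall]:
    """Unify SV sets across >=2 samples, recording per-sample raw evidence."""
    if len(calls_by_sample) < 2:
        raise ValueError("multi-sample unification needs >= 2 samples")
    callsets = []
    samples = list(calls_by_sample)
    for sample in samples:
        callsets.append(
            [replace(c, source_sample=sample) for c in calls_by_sample[sample]]
        )
    unified = merge_sv_callsets(callsets, window=window)
    for call in unified:
        for sample in samples:
            call.sample_evidence.setdefault(sample, False)
    return unified


def classify_private_shared(unified: list[SVCall]) -> dict[tuple, str]:
    """Label each unified call ``shared`` (evidence in >=2 samples) or
    ``private:<sample>``. Calls with no supported sample should have been
    pruned and raise."""
    labels: dict[tuple, str] = {}
    for call in unified:
        supported = [s for s, v in call.sample_evidence.items() if v]
        if not supported:
            raise ValueError(f"call {call.key} has raw evidence in no sample")
        labels[call.key] = (
            "shared" if len(supported) >= 2 else f"private:{supported[0]}"
        )
    return labels


def classify_sv_homology(call: SVCall) -> str:
    """Classify an SV as homologous (>100 bp junction homology) or
    nonhomologous (<=100 bp)."""
    if call.homology_len is None:
        warnings.warn(
            f"SV {call.key} lacks a homology length; treating as nonhomologous",
            stacklevel=2,
        )
        return "nonhomologous"
    return "homologous" if call.homology_len > HOMOLOGY_THRESHOLD else "nonhomologous"
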