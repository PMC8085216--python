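"""Evaluation metrics: SV matching, corroboration-based CN/ASCN scoring and
haplotype switch error."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .svcalls import SVCall

#: breakpoint match window for SV evaluation (the SV-identity rule)
MATCH_WINDOW = 100
#: fraction of a segment that must carry the true state to count as correct
CORROBORATION = 0.9


@dataclass
class PRF:
    precision: float
    recall: float

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


@dataclass
class EvalReport:
    categories: dict[str, PRF] = field(default_factory=dict)
    switch_error: float | None = None


def eval_svs(
    called: list[SVCall],
    truth: list[SVCall],
    window: int = MATCH_WINDOW,
    require_orientation: bool = True,
) -> PRF:
    """One-to-one SV matching within ``window`` bp (both breakpoints) with
    orientation agreement."""
    matched_truth: set[int] = set()
    tp = 0
    for c in called:
        best = None
        best_d = None
        for ti, t in enumerate(truth):
            if ti in matched_truth:
                continue
            if require_orientation and c.orientation != t.orientation:
                continue
            if (
                c.bp_a.chrom != t.bp_a.chrom
                or c.bp_b.chrom != t.bp_b.chrom
            ):
                continue
            da = abs(c.bp_a.pos - t.bp_a.pos)
            db = abs(c.bp_b.pos - t.bp_b.pos)
            if da < window and db < window:
                if best_d is None or da + db < best_d:
                    best, best_d = ti, da + db
        if best is not None:
            matched_truth.add(best)
            tp += 1
    fp = len(called) - tp
    fn = len(truth) - tp
    precision = tp / (tp + fp) if called else 0.0
    recall = tp / (tp + fn) if truth else 0.0
    return PRF(precision, recall)


def _clip_to_mask(segments, mask):
    """Intersect (chrom, start, end, state) segments with mask intervals."""
    if mask is None:
        return list(segments)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in mask:
        by_chrom.setdefault(chrom, []).append((s, e))
    out = []
    for chrom, s, e, state in segments:
        for ms, me in by_chrom.get(chrom, []):
            lo, hi = max(s, ms), min(e, me)
            if lo <= hi:
                out.append((chrom, lo, hi, state))
    return out


def _overlap_with_state(seg, others) -> int:
    chrom, s, e, state = seg
    covered = 0
    for oc, os_, oe, ostate in others:
        if oc != chrom or ostate != state:
            continue
        lo, hi = max(s, os_), min(e, oe)
        if lo <= hi:
            covered += hi - lo + 1
    return covered


def eval_cn(
    called,
    truth,
    corroboration: float = CORROBORATION,
    mask=None,
    min_length: int = 0,
) -> PRF:
    """Corroboration scoring of CN-state segments.

    ``called`` and ``truth`` are lists of (chrom, start, end, state); a
    called segment is correct iff more than ``corroboration`` of its length
    carries the true state, and symmetrically for recall over truth
    segments. ``mask`` restricts both sides to intervals (somatic mode);
    ``min_length`` drops shorter segments from both sides first.
    """
    called = [s for s in _clip_to_mask(called, mask) if s[2] - s[1] + 1 > min_length]
    truth = [s for s in _clip_to_mask(truth, mask) if s[2] - s[1] + 1 > min_length]
    if not called or not truth:
        return PRF(0.0, 0.0)
    correct_called = sum(
        1
        for seg in called
        if _overlap_with_state(seg, truth) > corroboration * (seg[2] - seg[1] + 1)
    )
    correct_truth = sum(
        1
        for seg in truth
        if _overlap_with_state(seg, called) > corroboration * (seg[2] - seg[1] + 1)
    )
    return PRF(correct_called / len(called), correct_truth / len(truth))


def eval_switch_error(called_phase: np.ndarray, truth_phase: np.ndarray) -> float:
    """Fraction of adjacent het-SNP pairs whose relative phase flips
    against the truth (a global flip is not a switch)."""
    called = np.asarray(called_phase).astype(int)
    truth = np.asarray(truth_phase).astype(int)
    if called.shape != truth.shape:
        raise ValueError("phase vectors must cover the same het sites")
    if len(called) < 2:
        return 0.0
    d = called ^ truth
    switches = np.count_nonzero(np.diff(d))
    return switches / (len(called) - 1)
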