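"""Allele-specific copy number (ASCN) by negative-binomial EM.

A segment with total integer CN mu can split its copies between the two
parental alleles in ceil((mu+1)/2) ways: {0, mu}, {1, mu-1}, ... Each
candidate split A_i = {A_i1, A_i2} is scored against the allelic read
depths o_j = (o_j1, o_j2) of the segment's heterozygous SNPs. Which allele
of a SNP sits on which copy-number track is latent, so the likelihood sums
over both orientations:

    p(o_j | a_j) = NB(o_j1 | b(p a_j1 + (1-p)), phi_1)
                 * NB(o_j2 | b(p a_j2 + (1-p)), phi_2)

with purity p (taken from the breakpoint-graph stage), haplotype base
coverage b and per-track dispersions phi (NB mean m, variance m + phi m^2;
dispersion is shared across the SNPs of a track — one observation per SNP
cannot identify a per-SNP value). A homozygously deleted track (a = 0) has
mean b(1-p): normal contamination only.

The EM marginalises the latent orientation. M-step updates for b (rate
ratio) and phi (moment matching on squared residuals) are accepted only if
the observed-data log-likelihood does not decrease, so the EM ascent
property holds by construction. The likelihood score of a state is its
likelihood normalised over all states of the segment, and the selected
split is the likelihood argmax; a selection is low-confidence when the top
score is below 0.8 or the segment has fewer than 5 heterozygous SNPs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

#: minimum likelihood score for a confident ASCN call
SCORE_CONFIDENT = 0.8
#: minimum heterozygous SNP count for a confident ASCN call
MIN_SNPS = 5
EM_TOL = 1e-6
EM_MAX_ITER = 500


@dataclass
class SnpDepth:
    position: int
    o1: int  # reads supporting allele 1
    o2: int  # reads supporting allele 2

    def __post_init__(self) -> None:
        if self.o1 < 0 or self.o2 < 0:
            raise ValueError("allelic depths must be >= 0")


@dataclass
class ASCNState:
    a1: int
    a2: int  # a1 <= a2; a1 + a2 = total CN
    b: float = 0.0
    phi1: float = 0.05
    phi2: float = 0.05
    loglik: float = -math.inf
    score: float = 0.0
    responsibilities: np.ndarray | None = None

    @property
    def pair(self) -> tuple[int, int]:
        return (self.a1, self.a2)

    @property
    def imbalanced(self) -> bool:
        return self.a1 != self.a2


def enumerate_allelic_states(mu: int) -> list[ASCNState]:
    """All ceil((mu+1)/2) splits {a, mu-a} of a total CN, a <= mu-a."""
    if mu < 0:
        raise ValueError("total CN must be >= 0")
    return [ASCNState(a, mu - a) for a in range(mu // 2 + 1)]


def _log_nb(o: np.ndarray, mean: float, phi: float) -> np.ndarray:
    """log NB pmf with mean/dispersion parameterisation (var = m + phi m^2)."""
    m = max(mean, 1e-9)
    if phi < 1e-8:
        return o * math.log(m) - m - gammaln(o + 1.0)
    r = 1.0 / phi
    return (
        gammaln(o + r)
        - gammaln(r)
        - gammaln(o + 1.0)
        + r * math.log(r / (r + m))
        + o * np.log(m / (r + m))
    )


def _state_loglik(
    o1: np.ndarray, o2: np.ndarray, a1: int, a2: int, b: float, p: float,
    phi1: float, phi2: float,
) -> tuple[float, np.ndarray]:
    """Observed log-likelihood marginalising orientation, plus per-SNP
    responsibility of the (a1 -> allele1, a2 -> allele2) orientation."""
    c1 = p * a1 + (1.0 - p)
    c2 = p * a2 + (1.0 - p)
    # orientation A: allele1 on the a1 track; orientation B: swapped
    la = _log_nb(o1, b * c1, phi1) + _log_nb(o2, b * c2, phi2)
    lb = _log_nb(o1, b * c2, phi2) + _log_nb(o2, b * c1, phi1)
    stacked = np.stack([la, lb]) + math.log(0.5)
    tot = logsumexp(stacked, axis=0)
    resp_a = np.exp(la + math.log(0.5) - tot)
    return float(tot.sum()), resp_a


def em_fit(
    state: ASCNState,
    snps: list[SnpDepth],
    p: float,
    total_cn: int | None = None,
) -> ASCNState:
    """Fit (b, phi1, phi2) for one candidate split by ascent-guarded EM."""
    if not snps:
        raise ValueError("em_fit needs at least one SNP")
    o1 = np.array([s.o1 for s in snps], dtype=float)
    o2 = np.array([s.o2 for s in snps], dtype=float)
    if o1.sum() + o2.sum() == 0:
        raise ValueError("no signal: all allelic depths are zero")
    mu = total_cn if total_cn is not None else state.a1 + state.a2
    denom = p * mu + 2.0 * (1.0 - p)
    # initialisation: b from median total depth, phi = 0.05, latent
    # orientation from the sign of o1 - o2
    b = max(float(np.median(o1 + o2)) / max(denom, 1e-6), 1e-3)
    phi1 = phi2 = 0.05
    c1 = p * state.a1 + (1.0 - p)
    c2 = p * state.a2 + (1.0 - p)
    resp = np.where(
        (o1 - o2) * (c1 - c2) > 0, 1.0, np.where(o1 == o2, 0.5, 0.0)
    )
    ll, _ = _state_loglik(o1, o2, state.a1, state.a2, b, p, phi1, phi2)
    for _ in range(EM_MAX_ITER):
        # E-step responsibilities at current params
        _, resp = _state_loglik(o1, o2, state.a1, state.a2, b, p, phi1, phi2)
        # track-wise expected observations
        w1 = resp
        w2 = 1.0 - resp
        # reads attributed to track 1 (CN a1): o1 under orientation A, o2 under B
        t1_obs = np.concatenate([o1, o2])
        t1_w = np.concatenate([w1, w2])
        t2_obs = np.concatenate([o2, o1])
        t2_w = np.concatenate([w1, w2])
        n_eff = t1_w.sum() + t2_w.sum()
        denom_b = t1_w.sum() * c1 + t2_w.sum() * c2
        b_new = float((t1_obs * t1_w).sum() + (t2_obs * t2_w).sum()) / max(denom_b, 1e-9)
        b_new = max(b_new, 1e-3)

        def phi_mm(obs, w, mean):
            if mean <= 1e-9 or w.sum() <= 0:
                return 0.0
            var = float((w * (obs - mean) ** 2).sum() / max(w.sum(), 1e-9))
            return float(min(max((var - mean) / mean**2, 0.0), 10.0))

        phi1_new = phi_mm(t1_obs, t1_w, b_new * c1)
        phi2_new = phi_mm(t2_obs, t2_w, b_new * c2)
        ll_new, _ = _state_loglik(
            o1, o2, state.a1, state.a2, b_new, p, phi1_new, phi2_new
        )
        if ll_new < ll - 1e-12:
            break  # guard: never accept a decreasing step
        improved = ll_new - ll
        b, phi1, phi2, ll = b_new, phi1_new, phi2_new, ll_new
        if improved < EM_TOL:
            break
    state.b = b
    state.phi1 = phi1
    state.phi2 = phi2
    state.loglik = ll
    _, state.responsibilities = _state_loglik(
        o1, o2, state.a1, state.a2, b, p, phi1, phi2
    )
    return state


@dataclass
class ASCNSelection:
    best: ASCNState
    confident: bool
    ranked: list[ASCNState] = field(default_factory=list)
    n_snps: int = 0

    def epsilon(self, state: ASCNState) -> int:
        """Penalty for adopting ``state``: proportional (constant 1) to the
        rank of its likelihood score; 0 for the selected state."""
        for rank, s in enumerate(self.ranked):
            if s.pair == state.pair:
                return rank
        return len(self.ranked)


def fit_segment_states(
    mu: int, snps: list[SnpDepth], p: float
) -> list[ASCNState]:
    """Fit every candidate split of a segment and normalise scores."""
    states = enumerate_allelic_states(mu)
    for st in states:
        em_fit(st, snps, p, total_cn=mu)
    logliks = np.array([st.loglik for st in states])
    w = np.exp(logliks - logsumexp(logliks))
    for st, sc in zip(states, w):
        st.score = float(sc)
    return states


def select_ascn(states: list[ASCNState], n_snps: int) -> ASCNSelection:
    """Pick the maximum-likelihood split; flag low confidence when the top
    score is < 0.8 or fewer than 5 SNPs support the segment."""
    ranked = sorted(states, key=lambda s: -s.loglik)
    best = ranked[0]
    confident = best.score >= SCORE_CONFIDENT and n_snps >= MIN_SNPS
    return ASCNSelection(best=best, confident=confident, ranked=ranked, n_snps=n_snps)
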