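# Methods

`karyograph` reconstructs cancer genome karyotypes from three data layers —
structural-variant (SV) calls, binned read depths, and heterozygous-SNP
allelic depths — by building a breakpoint graph whose edge multiplicities
are solved under the copy-number balance condition, splitting copy numbers
between alleles with a negative-binomial EM, phasing haplotypes against a
population panel, and enumerating Eulerian decompositions of the final
graph as candidate karyotypes. This note records the model, the parameters
that matter, and the design choices made where the design was genuinely
open.

## The breakpoint graph and the balance condition

A genomic segment is represented by a head (5′) and a tail (3′) node joined
by a *segment edge* whose integer multiplicity is the segment's copy number
(CN). *Reference edges* join reference-adjacent segment ends; *SV edges*
are novel adjacencies with orientation classes HH/HT/TH/TT read off the
attachment sides of the two sorted breakends (deletion-type = TH,
tandem-duplication-type = HT, inversion-type = TT/HH — the convention table
in `svcalls.py` is shared by the simulator and the file readers). At every
non-telomeric node the balance condition

    μ(e_s) = μ(e_r) + Σ_v μ(v)

must hold, which guarantees the graph decomposes into Eulerian paths
(linear chromosomes end at telomeres or at nodes left unbalanced by missing
evidence).

## Iterative refinement

Each iteration: (1) *local segmentation* — read depths in 100-bp bins are
segmented only inside regions pre-divided by the current SV breakpoints,
under a BIC criterion with Poisson likelihood and penalty λ·2k·log n (a
change-point adds two parameters, its position and a new rate; λ defaults
to 1 in the first round and 16 in the second, with 2000 available as a
noisy-data profile — the higher second-round penalty lets mis-segmented
regions without SV evidence merge back); (2) *purity/ploidy and integer
CNs* (below); (3) an exact integer program per *interrelated subset* of
nodes minimising total imbalance subject to the balance inequality, the
difference cap Σμ(v) ≤ |μ(e_s(s)) − μ(e_s(Adj_r(s)))|, and per-segment CN
domains (confident segments fixed; low-confidence segments choose between
their CN and the next-best state; segments under 50 bp, zero-length virtual
segments and no-depth segments range over [0, max CN]); (4) SV edges left
at multiplicity zero are false positives and are removed. Iterations repeat
until nothing is pruned; because the SV set shrinks monotonically this
terminates (cap 50).

Subsets are the BFS closures that always cross reference/SV edges and cross
a segment edge only at a non-confident segment; they share no variable, so
they solve independently. The absolute-value cap with variable segment
edges is encoded exactly with one sign binary per node (big-M disjunction).
The MILPs are solved with HiGHS via `scipy.optimize.milp`.

Ties are broken lexicographically by sequential exact solves: (1) minimum
imbalance; (2) maximum number of SV edges with positive multiplicity —
maximising the *count*, not the sum, is what rescues simple inversions and
balanced translocations from the null solution without inflating their
multiplicities through the slack a virtual segment opens; (3) segment
multiplicities closest to the initial CN estimates, where virtual segments
inherit their flank's CN as the anchor. On haplotype-expanded graphs two
further solves concentrate each SV's multiplicity onto as few track
candidates as possible (an SV arises on one haplotype) and split reference
flow out of collapsed balanced nodes evenly.

Exactly reciprocal SV breakpoints (a tail breakend at p and a head breakend
at p+1) would be nulled by the difference cap; a zero-length *virtual
segment* is inserted between them. Caller jitter usually separates such
breakpoints by a few bases, in which case the sliver segment (<50 bp, free
CN) plays the same role.

Between the two rounds, candidate adjacencies supported by read evidence
(≥3 reads) between unbalanced nodes are added as SV edges. Read-level
remapping is outside this package's scope: the support counts arrive from
files or from the simulator's truth-derived support map, which emulates
remapping discordant reads to candidate junction sequences. Candidates are
capped at 20 per node. In somatic mode, calls whose raw evidence matches
the control call set within 100 bp are excluded before iterating.

## Purity and ploidy

Copy ratios r_s (observed/expected counts; expected from the matched
control scaled to equal genome-wide totals, or flat without a control) are
fitted with a Gaussian mixture with component means m_q = (qp + 2(1−p))/D,
D = pτ + 2(1−p), over a grid p ∈ [0.40, 1.00] (step 0.01) and τ ∈ [1.5,
4.5] (step 0.05). Ratios alone cannot identify the model: relabelling every
state q as g·q with purity adjusted fits identically (the "ladder"
ambiguity familiar from purity/ploidy callers). The fit therefore uses, per
segment with enough SNPs, the mean folded B-allele-fraction deviation as a
joint likelihood term (expected deviation from the folded-normal mean for
the best allelic split of each q; a q = 0 state predicts balanced alleles —
residual normal contamination only — which stops large losses of
heterozygosity from being mis-modelled as homozygous deletions). Segment
votes are length-weighted with a model-misfit floor of 0.015 on the ratio
SE, segments under 30 bins do not vote, and a uniform outlier component
absorbs heterogeneous segments. Candidate optima (strong local maxima plus
their coarser ladder partners) are scored with a mild ploidy-parsimony
prior (0.2·|τ − 2.8|), and near-ties resolve to the smallest ploidy, then
the largest purity. A genuinely doubled genome defends itself through its
odd-CN states, which the halved model cannot fit; a perfectly doubled
genome with no odd states is reported at the parsimonious halved solution —
a known, irreducible limit of depth+allele data. The purity fit runs once
per refinement round.

Integer CNs are assigned per graph segment by highest posterior under the
mixture; ratios beyond the mixture's range fall back to rounding the
real-valued CN′ = (rD − 2(1−p))/p, flagged low-confidence when |CN − CN′| >
0.35. A segment is low-confidence when its posterior is below 0.95, it is
shorter than 50 bp or 30 bins, or it has no depth; the balance program may
then pick the recorded alternative state. The 30-bin rule extends the 50-bp
rule because at 100-bp bins the mean ratio of a ~kb segment is too noisy to
freeze — freezing it wrongly forces true junction multiplicities to zero.

## Allele-specific CN

A segment with total CN μ has ⌈(μ+1)/2⌉ candidate allelic splits {a, μ−a}.
Each is scored by an EM over the segment's het-SNP depths with NB
likelihood NB(o | b(pa + (1−p)), φ) per allele track (mean m, variance m +
φm²), marginalising the latent orientation of each SNP. b initialises from
the median total depth, φ at 0.05, responsibilities from the sign of
o1−o2; the b update is the exposure-weighted rate ratio and φ updates by
moment matching, each accepted only if the observed-data log-likelihood
does not decrease, so EM ascent holds by construction (tolerance 1e−6, cap
500 iterations). Dispersion is per track, not per SNP — one observation
per SNP cannot identify more. The likelihood score of a split is its
likelihood normalised over all splits of that segment; a selection is
low-confidence when the top score is below 0.8 or the segment has fewer
than 5 SNPs, in which case the allele-graph step may switch to an
alternative split at penalty ε/2 per node with ε = rank of the
alternative (proportionality constant 1).

Imbalanced segments expand into two haplotype-track node pairs. Within a
run of consecutive imbalanced segments the orientation of each split onto
the tracks minimises the junction imbalance (reference edges maximally
preserved, incident SV copies absorb the rest) plus ε penalties — solved
exhaustively for runs of ≤10 segments and by a left-to-right greedy pass
(ties keep the previous orientation) beyond. Edge multiplicities on the
expanded graph are then solved by the balance program, each original SV's
multiplicity distributed over its track-candidate edges (they sum to the
total).

## Haplotype phasing

Runs of imbalanced segments phase themselves: each het SNP goes to the
orientation with the higher NB likelihood under the run's (HSCN1, HSCN2);
exact ties go deterministically to track 1 with a flag. Two runs joined by
a *focal* (<1 Mb span) *nonhomologous* (≤100 bp junction homology) SV merge
into one haplotype segment with the track correspondence the SV's solved
haplotype implies — a nonhomologous mechanism acts on one allele.
Interchromosomal nonhomologous SVs are treated as merge-eligible (their
span is undefined). Homology lengths come from caller annotation or
simulator truth; a missing value is treated as nonhomologous with a
warning.

Balanced SNPs and the end-to-end orientation of the haplotype segments are
phased against a population panel with a constrained Viterbi pass over a
localized haplotype-cluster model: panel haplotypes collapse to their
distinct allele columns within 8-SNP windows, transitions follow
co-occurrence counts with recombination smoothing 1e−3, and the hidden
state is an ordered *pair* of clusters (a diplotype). Every site is
heterozygous, so an unconstrained site requires complementary alleles on
the two tracks; sites inside a phased block pin track 1 to the block's
allele up to the block's global flip, with mismatch probability 0.01. The
factorised max-product recursion keeps this O(windows · clusters³)
— a full haplotype-cluster phasing engine is out of scope; the contract is the constrained
argmax over this panel model, verified against exhaustive path enumeration
on small instances.

The haplotype graph assigns every segment two tracks: phased (HSCN1,
HSCN2) for imbalanced segments, μ/2 per track for balanced ones (an odd
balanced total is a contradiction and raises), and re-solves reference/SV
multiplicities per track.

## Karyotype enumeration and topology

For karyotyping, germline SV edges and short (<100 kb) simple SVs
(deletion/duplication-type junctions whose removal re-balances the flanks
after a compensating CN adjustment) are removed. Eulerian decompositions
are enumerated per connected component by a best-first search over partial
pairing states, prioritised by the entropy e = −Σ (w_i/w) log(w_i/w) of
the current path multiset (natural log; base is ranking-invariant), with
the frontier capped at a budget (default 1e5) — a deterministic
replacement for an unquantified branch-cutting rule. Low entropy prefers
few distinct paths at high multiplicity, the signature of duplication
processes. On small graphs the output contains every decomposition.

SV clusters are connected components of SV edges whose breakpoints fall
within a focal window (default 5 Mb, configurable; the original's precise
cluster definition is not public, so this formalisation is a documented
substitute) or share nodes, with ≥3 member edges. Classification: HSR =
amplification >10 copies with a reference-path connection to a telomere
that avoids the cluster's cycle edges; HSR/DM adds a cycle with every edge
multiplicity ≥5; DM = such a cycle without arm connection; deletion-type
chromothripsis (independent flag) = interspersed LOH, operationalised as
alternating minor-CN-0 segments among cluster members.

## The simulator

`simulate` builds molecules (ordered oriented reference segments, two
parental copies per chromosome), applies germline operators (deletion,
tandem duplication, inversion, block-interchange insertion; sizes
log-uniform 1–100 kb, so about half are under 10 kb), optional whole-genome
doubling, then somatic operators (additionally reciprocal translocation
and fold-back; chromothripsis, double-minute excision and
breakage-fusion-bridge cycles are available operators; sizes log-uniform
10 kb–5 Mb). The operator mix is uniform by default. Truth tables (SV
junctions with orientation and multiplicity, per-base total and
allele-specific CN, phased SNPs) derive deterministically from the
molecules; the same seed reproduces every artefact exactly (one seeded
generator, per-emitter substreams by fixed offsets).

Emitted data: NB bin counts around coverage·(p·cn_tumour + (1−p)·cn_normal)
per 100-bp bin with dispersion 0.02 (matched control at the germline CN);
het-SNP NB allelic depths around b(pa + (1−p)) at density 1/1500 bp; three
emulated callers that independently drop truth at the false-negative rate,
inject false positives at fp·|truth| with random coordinates and
orientations, and jitter breakpoints ±10 bp, with support/mapq drawn so
true calls pass the quality filter (<3 reads or mapq <20); junction
homology lengths 0–20 bp with a 10% homologous (101–300 bp) fraction; and a
phased panel containing the two truth haplotypes plus recombined
(switch rate 0.05/site), mutated (default 0.01) decoys.

The desk default is 2 chromosomes × 50 Mb with ~60 germline and ~20
somatic SVs — a 1:50 reduction of a ~3000 + ~200 whole-genome scheme;
purity 0.75 by default with 0.6/0.9 available, per-haplotype coverage
3–20× (default 15×). What the simulator does **not** model: read-level
artefacts (mappability, GC, alignment errors), sequencing error, subclonal
populations, and realistic per-type SV size spectra. Passing tests
therefore demonstrate the correctness of the graph algorithms and
estimators under NB noise and caller-style corruption, not performance on
real libraries. One visible consequence: three independent emulated
callers at fn = 0.1 miss almost nothing jointly, so end-to-end SV recall
runs well above what real callers achieve at 15×.

## Evaluation

SV matching is one-to-one within 100 bp on both breakpoints with
orientation agreement (a flag disables the orientation requirement). CN
and ASCN segments score by corroboration: a segment is correct iff more
than 90% of its length carries the true state, applied symmetrically for
precision and recall. In somatic (control-normalised) mode, CN evaluation
is restricted to regions where the control genome is plain diploid —
inside a germline CNV the control-normalised ratio does not measure the
tumour CN, so those (small) regions are excluded rather than rescaled.
Haplotype accuracy is the switch error rate: the fraction of adjacent
het-SNP pairs whose relative phase flips against truth (a global flip is
not a switch).

## Numerical choices and degenerate inputs

Empty regions segment to nothing; zero expected counts flag a segment
"no depth" instead of dividing; all-zero allelic depths are an error
("no signal"); an unidentifiable purity fit (a single ratio level) raises.
Solver determinism: BFS order is (segment, side); HiGHS is deterministic;
phasing ties and greedy ties have fixed resolutions. Iteration and
enumeration caps: 50 refinement iterations, 1e5 frontier states, EM 500
iterations.

## Known limitations

Ploidy of a perfectly doubled genome is reported halved (above). The
greedy run solver can be off by one junction-cost unit on adversarial
runs. The panel model is a simplification of haplotype-cluster phasing;
its switch error depends on panel quality in ways the real tool's does
not. Subclonal CN states, fractional CNs and read-level evidence are out
of scope.
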