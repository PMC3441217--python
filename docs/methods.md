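# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what passing tests on synthetic data do and do not
establish about real libraries.

## Unique tags, concordance and TPM

The unit of analysis is the *unique tag*: a distinct 18–30 nt DNA sequence
with per-replicate read counts.  U is mapped to T on input (sequencers
report T); tags containing N are dropped at the clean-read gate and
counted in the run manifest.  Technical-replicate concordance keeps only
tags with count ≥ 1 in both replicates and stores the arithmetic mean of
the two counts as a rational, never rounded before normalization.
TPM = count_mean / Σ count_mean × 10⁶ over all concordant tags of the
sample, so the TPM column always sums to 10⁶.

A consequence of concordance worth knowing at reduced depth: tag classes
with high sequence diversity and low per-tag abundance (the decoy
fragment classes here) lose most singleton tags, so the *concordant-tag*
class profile over-represents miRNAs relative to the *read-level*
composition.  At the depth of a real study (tens of millions of reads)
this distortion is negligible; at 10,000 reads/replicate it is visible,
which is why read-level composition claims are measured per replicate
before concordance.

## Annotation cascade

Annotation is exact substring matching against reference libraries in a
fixed priority order (miRNA first, then rRNA, tRNA, snRNA, snoRNA, scRNA,
srpRNA, piRNA, repeat, exon, intron, then the genome on either strand).
First hit wins; within a class, references are scanned in file order.
The miRNA test accepts either an exact substring of a precursor or an
isomiR-window alignment to a mature (shared with the isomiR module), so
templated end-variants and short non-templated 3' tails are annotated as
miRNA rather than leaking into the editing detector.  Matching is exact by
design: mismatched tags fall through the entire cascade, and single-
mismatch resolution is the editing detector's job.  The order of the
non-miRNA classes is a declared convention (structural RNAs before
piRNA/repeat before mRNA fragments) and configurable; nothing downstream
depends on it beyond determinism.

## IsomiR taxonomy

A miRNA tag's placement defines signed end offsets: d5 = tag 5' end −
mature 5' end (negative = 5' addition), d3 = tag 3' end − mature 3' end
(positive = 3' addition).  The sign pattern selects one of 8 categories
(or canonical at (0,0)); the full grid is in
`smallrna_devatlas.isomir`.  Choices:

- offset window |d5|, |d3| ≤ 5 nt — beyond that, a tag is not considered
  an isomiR of that mature (prevents cross-assignment between unrelated
  precursors; value is a knob);
- non-templated additions recognized at the 3' end only, ≤ 2 nt, and only
  when the tail *disagrees* with the precursor (otherwise the extension is
  templated); 5' additions must be templated;
- a tag placing in several precursors takes the placement minimizing
  |d5| + |d3| (ties: precursor id, then 5'-most placement).

Note one boundary effect: a tag whose terminal base differs from the
mature but aligns after removing it as a 1-nt non-templated tail has net
d3 = 0 and classifies as canonical-with-tail rather than as a terminal
editing event.  Terminal mismatches are intrinsically ambiguous between
editing and end-modification; the editing detector flags positions 1 and
L as `end_ambiguous` for the same reason.

## Editing detection

Candidate events are tags of the same length as some mature at Hamming
distance exactly 1 (no indels), taken only from tags that survived no
annotation (unannotated or genome-only).  Events at (mature, position)
pairs present in the SNP table are removed.  A tag at distance 1 from
several matures yields one flagged event per mature.  Events are profiled
by 1-based mature position with seed = 2–8 and flank = 12–15; the
positional enrichment ratio is the mean per-position TPM inside
seed ∪ flank over the mean elsewhere (undefined with no events; infinite
when no editing TPM falls outside seed ∪ flank — in reports that need a
bounded number, the seed+flank TPM *share* is used instead).  The
high-confidence gate is strictly TPM > 50, exposed as a parameter.  The
summary's edited-read fraction uses Σ event TPM / (Σ event TPM +
Σ miRNA-class TPM); whether edited reads belong in the denominator is not
fixed by the underlying design, so the choice is declared here and
configurable in spirit (the components are returned separately).

The detector deliberately has no per-event statistical test; the
error-control burden sits on replicate concordance plus the TPM gate, as
in the original design.  The feasibility arithmetic matters: at 10,000
reads/replicate a tag present once in each replicate already measures
~100 TPM, so *any* sequencing-error tag that recurs in both replicates is
a false event above the 50-TPM gate.  With per-base error rate e, mature
length L ≈ 22, canonical fraction p, and per-miRNA read counts rᵢ, the
expected number of concordant error tags per stage is ≈ Σᵢ 66·λᵢ² with
λᵢ = rᵢ·p·(L·e)/66, and the log-normal abundance law inflates Σᵢ rᵢ² by
e^{σ²} ≈ 4.2.  Zero false events at the gate in ≥95% of runs therefore
requires e ≲ 2×10⁻⁵.  The generator's default residual error rate is
1×10⁻⁵ — representing a stringently quality-filtered clean-read set — and
this derivation is the reason.

## Hairpin folding and novel-miRNA calling

The folder minimizes a stacking-energy objective over nested structures by
dynamic programming.  Energies are integers in tenths of a kcal/mol
(exact ties, deterministic 5'-most tie-breaking): stacked-pair energies by
pair class (GC/GC −3.3, GC/AT −2.2, AT/AT −1.1, wobble G:T weaker),
hairpin-loop, bulge and internal-loop penalties from small tables with
logarithmic extrapolation, a flat multiloop-closing penalty, and minimum
hairpin loop 3.  Interior loops are capped at 30 nt per side, which is
exact for all sequences short enough to enumerate and a standard bounded
approximation above that.  The magnitudes approximate nearest-neighbor
scales so that the classical −18 kcal/mol precursor threshold is
meaningful, but absolute values are not those of a full thermodynamic
folder; all specificity claims rest on planted-versus-shuffled contrasts,
not absolute energies.  `structure_energy` re-scores any dot-bracket
structure by loop decomposition and always reproduces the folder's
reported energy; an exhaustive enumeration of nested structures is the
oracle in the test suite.

Candidate calling embeds each genome-mapped 18–26 nt tag in two windows
(tag on the 5' or 3' arm: 10 nt flank + tag + 35 nt maximal loop + tag +
flank), reverse-complementing minus-strand windows.  Acceptance requires
energy ≤ −18 kcal/mol, no base of the mature paired with another mature
base, ≥ 14 mature bases paired into the star region, ≥ 60% of the mature
paired, star–mature gap ≤ 35 nt, and both flanks ≥ 10 nt.  The star is
constrained to the best mature-length (+2 nt) window of partner
positions — the star strand is a Dicer product of about mature length —
which is what gives the caller its specificity: without the constraint,
scattered partner positions in shuffled controls count toward the duplex
and false acceptance roughly doubles.  The 2-nt 3'-overhang geometry test
is reported as a flag (mature 5' end paired within 1 nt; 2 ± 1 nt
unpaired at the loop-facing mature 3' side) and is not a hard filter by
default.  Dinucleotide-shuffled controls use the Altschul–Erickson
edge-permutation method with the mature re-implanted at its offset.

## Stage profiles

Z-standardization is per row over stages with the *population* SD
(the defining equation carries no ddof); all-constant rows are set to
Z ≡ 0 by convention.  Complete-linkage clustering is implemented directly
(O(n³) agglomeration): merge the pair with the smallest maximal
inter-member distance, ties broken toward the smallest cluster-index
pair, leaf order by recursive traversal with the lower-index subtree
first.  scipy's implementation is the independent cross-check in the
tests; the in-package version exists because deterministic tie-breaking
is part of the contract.  Default metric: euclidean on Z rows
(standardize-then-cluster; correlation distance available).  Replicate
correlation is Pearson on log₁₀(count + 1) over the union of detected
ids.  Abundance tiers use strict inequalities at 300 and 1000 TPM.
Pattern archetypes: Spearman ρ with stage index ≥ +0.7 → increasing,
≤ −0.7 → decreasing; else a strictly interior extremum with ≥ 2×
prominence against the endpoint mean → mid-peak / mid-trough; else flat,
the explicit residual class.  Both ρ = 0.7 and the 2× prominence are
stated defaults, not claims; on short noisy series (~6 stages) a
genuinely flat row crosses |ρ| = 0.7 in roughly 15% of draws, so flat
assignments are the least reliable — categorization needs ≥ 4 stages and
is reported, not filtered on.

## The synthetic-data generator

The generator defines the study conditions: by default 3 stages × 2
technical replicates × 10,000 reads, 60 miRNAs, class mixture dominated by
miRNA (0.68, plus 0.02 "novel"), mature lengths 20–24 nt, all 8 isomiR
categories producible with 3' trimming dominant (category 7 at 0.15 of
miRNA reads; isomiRs total 0.31), six A→G editing events planted on
abundance-anchored miRNAs at seed (3, 5, 6, 8) and flank (13, 14)
positions with stage-increasing frequencies (one linear 0.2→0.8 ramp
crossing the wild type mid-course), three heterozygous-like SNP positions
(alt fraction 0.5) on other anchors, and an rRNA proportion tripled at
stage 0 (an early-development rRNA peak).

Abundance law: per-miRNA base weights are log-normal (σ = 1.2); anchor
miRNAs get a fixed weight (4.0, ≈ 2–4% read share) so planted events sit
far above the detection floor, mirroring the fact that editing is
reported on well-expressed miRNAs.  Stage structure multiplies weights by
archetype shapes (geometric 8× ramps; triangular-in-log mid-peak/trough)
assigned round-robin to non-anchor miRNAs.  Each replicate re-draws a
small log-normal jitter (σ = 0.25) of every weight before multinomial
sampling; pure multinomial resampling alone would put the replicate
correlation at r ≈ 0.99 on log₁₀(count+1), whereas real technical
replicates of this kind sit near r ≈ 0.9 — with the jitter the generator
lands at r ≈ 0.93–0.96.  No claim is made that real libraries are
log-normal; it is a stand-in with the right qualitative shape (a few
dominant species, a long low tail).

Precursors are built as arm + loop + reverse-complement(arm), with 5
templated nt on each side of the mature (so templated isomiR additions
are realizable) and an 8-nt loop; they fold into deep stems by
construction.  Novel precursors are placed in the genome but withheld
from the reference libraries, so their reads annotate genome-only and
exercise the hairpin caller end to end.  Decoy class references are
random sequences (60–200 nt) from which reads are drawn as substrings —
they model "derived-from" fragment classes, not real rRNA/tRNA biology.
Edited and SNP-alt reads are emitted at canonical length (no isomiR
offsets on the same read), keeping every planted mismatch recoverable as
a Hamming-1 event; reads hit by simulated sequencing errors are labelled
as such in the ground truth and carry no recoverable class expectation.

What passing on this generator shows: the pipeline's logic is correct and
its planted-truth recovery is calibrated at desk scale.  What it does not
show: robustness to adapter artifacts, quality-score structure,
multi-mapping, paralogous miRNA families, non-uniform error profiles, or
real secondary-structure thermodynamics — none of which the generator
emulates.

## Problem sizes and determinism

Default analyses run 3 stages × 2 × 10,000 reads; the test suite uses
20 seeded repetitions of that scenario, 50 planted precursors with 100
shuffled controls each for the hairpin contrast, and enumeration oracles
at ≤ 22 nt — sizes chosen so the whole suite completes in a few minutes
on one CPU while keeping every statistical margin ≥ 3σ.  All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
identical configurations produce byte-identical outputs, and the pipeline
manifest records inputs, parameters, version and seed for every run.
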