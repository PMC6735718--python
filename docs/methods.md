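# Methods

This note documents the model, the tunable parameters, the numerical
choices, and what the built-in simulator does and does not emulate.

## Signature model

A *signature* is one read's evidence for a candidate SV: the quadruple
(type, chromosome, begin, end) plus its evidence class (intra- or
inter-alignment) and the read it came from. All coordinates are 0-based
half-open; only the VCF writer converts to 1-based.

For insertions the interval is `[begin, begin + inserted_length)`: the
span encodes the inserted length rather than a reference footprint, so
span comparisons during clustering compare inserted lengths and two
same-length insertions at the same point cluster tightly. The evaluation
harness uses the matching convention (insertion-point distance plus
inserted-length ratio) for the same reason — interval overlap is
meaningless for point events.

### Intra-alignment extraction

Deletion (D) and insertion (I) CIGAR runs of at least `min_sv_size`
(default 50 bp — the conventional lower bound of the SV size regime) are
reported. Same-type runs separated by at most `gap_merge_tolerance`
(10 bp) aligned bases are merged first, because indel sequencing errors
shatter single events into adjacent runs; without merging, a noisy 200 bp
deletion frequently surfaces as two sub-threshold fragments.

### Inter-alignment extraction

Split alignments are examined one read at a time, segments ordered along
the read (read coordinates are reconstructed from clip lengths, with clip
roles swapped on the reverse strand; hard clips count like soft clips).
Consecutive triples are checked before pairs, and pairs consumed by a
firing triple rule are skipped:

* **INV** — strand pattern `+,−,+` (or `−,+,−`) with the middle segment
  between the flanks: inversion over the middle segment's interval.
* **DUP** — flanks reference-adjacent (junction gap below
  `segment_gap_tolerance`, 100 bp) and the middle segment mapping
  elsewhere (other chromosome, or ≥ `min_distance` = 10 kb away):
  duplication inserted at the junction with the middle segment's interval
  as origin.
* **DEL / INS** — same chromosome and strand, junction gap below
  `min_distance`: a reference gap exceeding the read gap by
  ≥ `min_sv_size` is a deletion; the converse is an insertion whose span
  is the unaligned read length.
* **TAN** — backward reference jump of ≥ `min_sv_size` but less than
  `min_distance`: tandem duplication over the re-traversed interval.
* **BRK** — any remaining junction between distant loci (other
  chromosome, strand flip, or a forward/backward jump of ≥ `min_distance`)
  yields one breakend per side, each holding the other side as mate.

The `min_distance` cap on DEL and TAN is deliberate: reads that end
inside a duplication's origin segment otherwise produce a pair whose
backward jump spans the whole origin–destination distance and would be
misread as a giant tandem duplication (or, forward, as a giant deletion).
Classifying such junctions as breakends instead leaves them available for
insertion–breakend pairing and keeps the interval classes bounded by the
size regime the caller targets. Reads split into more than 10 segments
are skipped as likely mapping artifacts, which also bounds the clique
stage. These thresholds are heuristic by nature; all are exposed as
function arguments.

## Clustering

Signatures are bucketed by (type, chromosome); within a bucket an edge
joins two signatures when their span-position distance is **strictly**
below `T` (default 0.7). `N` (default 900 bp) converts positional offset
into span-difference units. Pairs whose positional difference alone
forces `PD/N ≥ T` are rejected without computing the span term; this
pruning provably cannot change the graph (SPD ≥ PD/N).

Decisions where the metric definition left room:

* The "position" entering both PD and the score's `s_pos` is the interval
  midpoint, matching the midpoint term of PD itself.
* Two zero-span signatures (breakends) get SD ≡ 0, so breakend clustering
  degenerates to positional clustering; breakend edges additionally
  require the mate loci to be within `N·T` bp of each other.

Clusters are the maximal cliques of the graph (networkx's Bron–Kerbosch
implementation with pivoting; the test suite checks it against
brute-force subset enumeration). Maximal cliques may share vertices, but
each signature should support one variant only, so cliques are consumed
greedily in decreasing order of (size, preliminary score, leftmost
position), removing already-taken signatures from later cliques. The
consensus interval of a cluster is the member-wise median of begins and
ends (and of origin coordinates for DUP clusters): robust against the
occasional truncated signature from a read that only partially covers the
event.

### Scoring

`S = n + b + sp + ss`, clamped into (0, 100]. Standard deviations are
population (not sample) standard deviations so that singleton clusters
score 0 dispersion rather than dividing by zero. For all-breakend
clusters `span̄ = 0`; the consistency terms then award their maximum when
the corresponding standard deviation is 0 and nothing otherwise. The
clamp to a minimum of 1 keeps pathological components inside the stated
open-lower-bound range.

At 6× coverage the count component saturates around `n ≈ 12`, so even
perfect clusters score in the 40–75 range; score cutoffs should be chosen
relative to coverage.

## Combination

Insertion clusters are paired 1-to-1 with breakend clusters at most
`match_distance` (100 bp) away, nearest first, ties to the
lower-coordinate insertion; each breakend is used at most once. A paired
insertion becomes an interspersed duplication whose origin starts at the
breakend's mate position and extends by the inserted length. Breakends
without a partner are dropped — translocation calling is out of scope.
Cut&paste annotation requires at least one shared base (half-open
semantics) between the origin and a deletion call; it is an annotation
only, the class stays `interspersed_duplication`, since copy-and-delete
cannot be distinguished from cut-and-paste by reads alone.

## VCF encoding

Records follow the common symbolic-allele convention: POS is the base
*before* the event (numerically the 0-based begin), END the last affected
base for interval classes, and END = POS for insertion-class records,
with SVLEN negative for deletions. This keeps POS/END/SVLEN mutually
consistent under htslib's record-length rules, which derive the record
span from SVLEN for symbolic alleles. Duplication origins are encoded as
CHR2/POS2/END2 plus the CUTPASTE flag.

## Simulator

The simulator replaces a read simulator and an aligner. It draws an
i.i.d. uniform A/C/G/T reference, implants non-overlapping variants
(deletion removes, inversion reverse-complements, tandem duplication
doubles in place, interspersed duplication copies a distant origin
≥ 20 kb away, novel insertion adds random sequence), and tiles the donor
with reads whose lengths are log-normal, median 8 kb, truncated to
[500 bp, 50 kb] — a generic long-read length profile. For every read it
emits the records an idealized aligner would produce, by construction
from the known donor-to-reference block map: D/I CIGAR runs for events
within a colinear stretch, split supplementary records with correct
strands across inversions and duplications. Zygosity `het` makes the
second haplotype the unmodified reference, so half of the reads carry no
variant.

Noisy mode scatters 1-bp indel errors through every aligned block at
configurable rates (defaults 6% insertion, 3% deletion, plus ~1%
substitutions which do not alter CIGAR geometry — an insertion-heavy
~10% profile typical of raw PacBio reads). Reference block boundaries
are preserved exactly, emulating an aligner that recovers the true
breakpoints; what noise exercises is gap merging, span/position jitter
and spurious singleton signatures, **not** breakpoint drift, chimeric
reads, repeat-induced mismapping, or coverage biases. Default variant
counts (200 deletions, 100 inversions, 100 tandem and 200 interspersed
duplications) and the 50 bp – 10 kb size range mirror the scale of
standard SV-simulation benchmarks; desk-scale runs in the tests use a
500 kb genome with 60 variants of 50–500 bp at 6× coverage so the whole
suite stays fast. Passing tests on this generator demonstrate correct
geometry handling and clustering arithmetic; they do not demonstrate
robustness to real alignment artifacts.

## Known limitations

* Genotyping, nested SVs and standalone translocations are not called.
* Signature extraction relies on gaps and split geometry only; high-
  mismatch-pileup evidence is not used.
* The insertion–breakend pairing arbitrates multi-breakend junctions
  greedily by distance; complex loci with several nearby junctions may
  pair suboptimally.
* Graph construction is O(n²) per (type, chromosome) bucket after
  positional pruning; extremely deep coverage of a single locus is
  bounded only by the per-class count cap downstream.
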