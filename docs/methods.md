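# Methods

## Junction model and microhomology definition

A deletion junction is modelled by three sequences: the proximal reference
flank (retained 5' sequence running into the deleted interval), the distal
reference flank (deleted sequence running into the retained 3' flank), and
the sequenced junction fragment.  Regions default to 150 bp with the
breakpoint between nucleotides 75 and 76, the same convention used for the
artificial control breakpoints, so observed and control regions are
directly comparable.

Microhomology is defined operationally as **two-sided extension at the
mapped breakpoints**: walking outward from the breakpoint of each reference
flank, count the bases on which the two references agree (5' extension plus
3' extension; N never matches).  Junction studies of this kind traditionally
judge microhomology from multiple sequence alignments by eye, which is not
algorithmic; the two-sided extension rule is the standard formalisation of
that procedure, it is applied identically to observed junctions and to
control pseudo-junctions, and for an insert-free
junction it provably equals the maximum over every split parse of the
junction (`lcp + lcs − length`), which is what the brute-force oracle in
the test suite enumerates.

The observed junction is compared against the junction expected from the
mapped breakpoints.  Deviations are classified as:

* **substitution scars** — equal-length mismatched blocks of ≤ 2 bases;
* **deletion scars** — ≤ 2 reference bases absent from the junction;
* **insertions** — novel junction bases, which force mh = 0 (a parse
  implying both an insert and microhomology is rejected as contradictory).

Scars are only recognised within 10 bp of the switch point and at most 2
events per junction (matching the 1–2 nt scars actually observed); junctions
needing more editing are reported unmappable, as are junctions without ≥ 10
exactly matching anchor bases on each side.  Among equal-mh parses the
leftmost switch point is reported; this shifts refined breakpoint
coordinates but never the mh length, which is the quantity used downstream.
A consequence of trusting the mapped breakpoints is that a 1-bp deletion
scar at a blunt junction is distinguishable from a blunt junction mapped one
base over — pure sequence parsing cannot make that distinction, the prior
breakpoint location can.

Refined breakpoints follow the convention: the proximal breakpoint is the
last nucleotide 5'-adjacent to the microhomology stretch, the distal
breakpoint the first nucleotide 3'-adjacent to it.  Deletion size is
`end − start` of the 1-based breakpoint positions, the only definition that
reproduces every printed kb value of the bundled table.

## Mechanism classification

* mh = 0 → group 1, NHEJ (scars noted in the rationale).
* mh ≥ 1 with same-superfamily repeats at both breakpoints → group 2,
  `NAHR/Replicative/MMEJ` for mh ≥ 5, `NAHR/Replicative/NHEJ` otherwise.
  The short-mh same-family combination never occurs in the cohort, so that
  branch extends the mh-length rule and flags itself as extrapolated.
* otherwise → group 3, `Replicative/MMEJ` (mh ≥ 5) or `Replicative/NHEJ`.

"Same family" means the same superfamily bucket (AluJo–AluSz pair, L1PA4–
MIRb do not) under the mapping Alu\*→Alu, L1\*→L1, MIR\*→MIR,
LTR/MLT/THE→LTR, Tigger/Charlie/Mer→DNA, else Other — the only mapping
consistent with all 24 bundled mechanism calls.  NAHR is never the sole
candidate; pairwise repeat identity ≥ 90% adds a MEPS-compatible note
(minimal efficient processing segment) to the rationale rather than
changing the call.  The MMEJ threshold of 5 bp follows the usual
NHEJ (1–4 bp) / MMEJ (≥ 5 bp) division.

## Architecture scanners

All scanners operate on 150-bp regions and are applied identically to
observed and control regions, so enrichment comparisons are internally
consistent even where a scanner is a surrogate for an external tool.

* **Motifs** — IUPAC patterns from an editable TSV catalogue, scanned with
  overlaps on both strands when flagged.  The bundled default catalogue
  holds 40 rearrangement-associated motifs (chi-like elements, translin
  targets, Ig class-switch repeats, topoisomerase cleavage consensi,
  polymerase pause/frameshift hotspots, V(D)J signal sequences,
  purine/pyrimidine and alternating tracts, common repeat cores); any
  catalogue in the same schema can be dropped in, since the exact motif list
  behind the bundled per-region counts is not recoverable.
* **Direct/inverted/mirror repeats** — maximal arm pairs (identical,
  reverse-complement, reverse) with arm ≥ 8 bp, spacer ≤ 120 bp, arms
  inside the region.  Arms with base-composition entropy ≤ 1 bit
  (homopolymers, plain dinucleotide repeats) are suppressed to avoid
  trivially dense calls.
* **Tetraplex** — quadruplex candidates assembled from four maximal G-runs
  (each ≥ 2 Gs) within a 30-bp span, scored by
  `20·(x − 2) + (30 − span) − Σ pairwise loop differences` with *x* the
  shortest run; the formula rewards longer runs, compact span and even
  loops, and overlapping candidates reduce to the best per locus.  This is
  a documented stand-in for QGRS-style G-scores, whose exact formula is not
  available in a reimplementable form.
* **Z-DNA** — maximal alternating purine–pyrimidine tracts built from
  GT/GC/AC dinucleotide steps, ≥ 12 bp, scored by length.  This surrogate
  captures the GT-repeat intent of statistical-mechanical Z-DNA scoring
  without reimplementing it.
* **Flanking filter** — a non-B feature counts only if its counterparts
  flank the breakpoint: two-armed features need one arm on each side (or an
  arm overlapping the breakpoint), single tracts must overlap it.
* **Repeat intersection** — the annotated repeat containing the breakpoint
  position; ties go to the longest overlap with the 150-bp region.
  Pairwise identity between repeats uses global alignment (match +1,
  mismatch −2, gap open −5, gap extend −2), reported as
  100 × matches/columns rounded to an integer.

## Control population and statistics

Controls are 500 N-free 150-bp windows drawn uniformly from a reference
(any FASTA; the bundled workflows use the synthetic locus, keeping the
pipeline download-free).  Control microhomology needs two flanks, but a
control region carries a single artificial breakpoint, so region *i* is
paired cyclically with region *i + 1* — preserving n = 500 pseudo-junctions — and
measured by the same caller with zero scar tolerance.  For iid uniform
sequence this yields P(mh = 0) = 9/16 and P(mh ≤ 1) = 27/32 analytically,
the 0–1 bp cluster the control distribution is expected to show.

Fisher tests are two-sided (sum of all tables with the observed margins
whose point probability does not exceed the observed one), delegated to
scipy and cross-checked against exact enumeration in the tests; degenerate
margins return p = 1 by convention.  The Wilcoxon rank-sum test uses
midranks, enumerating the exact permutation distribution for combined
samples ≤ 20 and the tie- and continuity-corrected normal approximation
otherwise.  Family-level repeat tests (Alu, L1) are Bonferroni-corrected
with k = 2 (the number of families tested); per-motif tests with k = the
catalogue size.  The per-motif comparison is presence/absence per region;
occurrence totals enter through the motif-density Wilcoxon comparison, so
both readings of "per-motif comparison" are reported.

## Synthetic data: what it emulates and what it does not

The generator produces an iid background locus at a chosen GC with planted
decoy cassettes (Alu-like 300 nt, L1-like 2 knt, MIR/DNA/LTR decoys) whose
annotations are exact, and plants deletion alleles with controlled
signatures.  Microhomology is planted by copying the mh bases 5' of the
proximal breakpoint over the distal flank, forcing mismatches at both
extension boundaries, and rejecting draws where the junction admits a
longer accidental parse — so planted signatures are the unique maximal
parse and recovery tests are exact rather than probabilistic.  Decoy copies
carry substitutions only (2–15% per copy, or an explicit arm-divergence
setting), which spans the 74–96% identity range seen between repeat pairs
in the cohort and makes the generator's Hamming identity an exact truth for
the aligner to match.

Limitations: cassettes are random consensi, not real repeat sequence, so
repeat content statistics (e.g. how often random control breakpoints hit a
repeat) reflect the planted density (default 0.2), not genomic reality —
the synthetic repeat-enrichment p-values are directional checks, not
reproductions of the bundled table's original values, which depended on a
genome-drawn control.  The cohort builder realises each bundled record's
microhomology, scar and repeat-family context but not its deletion size
(up to 5.5 Mb, irrelevant to junction signatures) nor its motif/non-B
counts, which depend on the real hg19 sequence context.  Complex
rearrangements with more than one template switch are out of scope; the
two-deletion complex case is represented as two independent junctions.

## Problem sizes and numerical choices

Default study conditions: 24-case cohort on a 300-kb locus at repeat
density 0.2; controls n = 500 from an 800-kb reference; analytic
microhomology checks use 2 000 pseudo-junctions from a repeat-free uniform
locus.  Scanner oracle-equivalence tests run 1 000 random strings of
30–200 nt.  All randomness flows through numpy Generators seeded from the
user-supplied seed; identical seeds give byte-identical loci, cohorts and
controls.  Rounding is half-up for kb sizes and identity percentages.
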