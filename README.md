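# junctionsig

Breakpoint-junction signature analysis for non-recurrent microdeletions:
microhomology calling, genomic-architecture scanning, random-control
enrichment statistics, and repair-mechanism classification.

## The problem

Non-recurrent copy-number deletions scatter their breakpoints and leave no
recombination hotspot, so the only evidence about how each one arose is the
*breakpoint signature*: the microhomology, inserted bases, and information
scars visible at the sequenced junction, together with the local genomic
architecture (repeat elements, sequence motifs, non-B DNA-forming sequences)
of the two 150-bp breakpoint regions.  This package implements that analysis
for the cohort of 24 fine-mapped microdeletions of the FOXL2 locus (the BPES
region on chromosome 3): 16 deletions removing the gene and 8 removing only
upstream regulatory sequence, whose summary table is bundled as a fixture.
It is aimed at anyone dissecting structural-variant junctions — the same
machinery applies to any locus once junctions are sequenced.

## The method

For a junction with proximal reference flank *P* (breakpoint after position
*p*) and distal flank *D* (breakpoint before position *d* + 1),
microhomology is the two-sided extension

    mh = max{k : P[p-k..p-1] = D[d-k..d-1]} + max{k : P[p..p+k-1] = D[d..d+k-1]}

— the bases flanking the switch point that match *both* references.  The
observed junction is compared with the expected junction `P[:p] + D[d:]`;
small deviations near the switch point are emitted as information scars
(1–2 bp substitutions, 1-bp deletions) or an untemplated insertion.
Signatures then classify each deletion:

* **group 1** — perfect transition (mh = 0): NHEJ, possibly with a scar;
* **group 2** — mh ≥ 1 plus same-superfamily repeats (Alu–Alu, L1–L1) at
  both breakpoints: NAHR candidate alongside replicative template switching
  (FoSTeS/MMBIR/SRS/BISRS) and MMEJ (mh ≥ 5) or NHEJ (mh 1–4);
* **group 3** — mh ≥ 1 without a same-superfamily pair: replicative
  mechanisms with MMEJ or NHEJ by the same mh cutoff.

Enrichment against a random control population (500 sequences of 150 bp,
artificial breakpoint between nt 75 and 76) uses two-sided Fisher exact
tests on presence/absence tables and Wilcoxon rank-sum tests on
distributions.  For iid uniform flanks, control microhomology follows
P(mh = 0) = (3/4)² = 0.5625 and P(mh ≤ 1) = 27/32 — it clusters at 0–1 bp.

## Worked example

The `analysis/` scripts run the study end to end on synthetic data (a
generated locus with planted repeat cassettes and one planted junction per
cohort record; no downloads).  With seed 1:

```
$ python analysis/02_call_junctions.py 1
junctions with microhomology: 22/24 (91.7%)
calls agreeing with the bundled table: 24/24

$ python analysis/05_classify_mechanisms.py 1
group census: 2 perfect-transition (NHEJ) / 9 same-family-repeat (NAHR candidates) / 13 microhomology-only
classifications containing NAHR: 9; Replicative without NAHR: 13
pipeline vs table agreement: 24/24
```

22 of 24 junctions carry microhomology (91.7%); the two exceptions are the
perfect-transition deletions, one of which shows a del(T) information scar.
The classifier reproduces the bundled mechanism column for all 24 records
and the 2/9/13 group split.  `analysis/04_control_enrichment.py` adds the
control comparison: control microhomology sits at the analytic 0–1 bp
cluster (P(mh = 0) ≈ 0.56–0.59) while the observed cohort's 22/24 presence
is enriched at p < 10⁻⁶, and writes the full contingency battery to
`results/enrichment.tsv`.

Library use mirrors the scripts:

```python
from junctionsig import make_table1_like_cohort, call_microhomology

cohort = make_table1_like_cohort(seed=1)
call = call_microhomology(cohort.cases[7])   # deletion 8
call.mh_len                                   # 66 — the longest stretch
```

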