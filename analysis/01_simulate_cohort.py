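"""Build the synthetic study materials.

Generates a synthetic reference locus with planted repeat cassettes, realises
one junction case per record of the bundled 24-deletion table (matching each
record's microhomology, scar, and repeat-family context), and writes:

* results/locus.fa             — the synthetic reference
* results/locus_repeats.out    — RepeatMasker-style annotations
* results/junction_regions.fa  — proximal/distal references and junction
                                 fragment per case (bp=75 headers)
* results/cohort_truth.tsv     — planted ground truth per case
"""

import sys
from pathlib import Path

import pandas as pd

from junctionsig import make_table1_like_cohort, write_fasta
from junctionsig.io_model import write_repeatmasker_out

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cohort = make_table1_like_cohort(seed=SEED)

write_fasta([cohort.locus], OUT / "locus.fa")
write_repeatmasker_out(cohort.annotations, OUT / "locus_repeats.out")

regions = []
for case in cohort.cases:
    regions.append(case.proximal_ref)
    regions.append(case.distal_ref)
write_fasta(regions, OUT / "junction_regions.fa")

rows = []
for case, truth in zip(cohort.cases, cohort.truths):
    rows.append({
        "case_id": case.case_id,
        "start": truth.start,
        "end": truth.end,
        "mh_len": truth.spec.mh_len,
        "scar": truth.spec.scar or "-",
        "family_prox": truth.family_prox or "-",
        "family_dist": truth.family_dist or "-",
        "identity_pct": truth.identity_pct if truth.identity_pct is not None
        else "-",
        "expected_mechanism": truth.expected_call.mechanism_string(),
    })
pd.DataFrame(rows).to_csv(OUT / "cohort_truth.tsv", sep="\t", index=False)

print(f"locus: {len(cohort.locus.seq):,} nt, "
      f"{len(cohort.annotations)} repeat cassettes")
print(f"cohort: {len(cohort.cases)} junction cases -> {OUT}")
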