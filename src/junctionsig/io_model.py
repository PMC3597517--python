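"""Domain types and file I/O for breakpoint-junction analysis.

The deletion cohort studied here comprises 24 non-recurrent microdeletions of
the FOXL2 locus on chromosome 3 (blepharophimosis syndrome, BPES): 16 deletions
removing the gene itself (patients 1-16) and 8 removing only upstream
regulatory sequence (patients A-H).  Each deletion is summarised by its hg19
breakpoint coordinates, the microhomology and scar observed at the sequenced
junction, the repeat elements intersecting each breakpoint, and per-breakpoint
counts of sequence motifs and non-B DNA-forming sequences.  That summary table
ships with the package as a TSV fixture.

Coordinate conventions: genomic intervals are stored 0-based half-open
internally; the fixture's breakpoint positions are 1-based and converted at the
boundary.  A ``SequenceRegion`` breakpoint lies between 1-based positions
``breakpoint_offset`` and ``breakpoint_offset + 1``.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class JunctionSigError(Exception):
    """Base class for package errors."""


class FormatError(JunctionSigError):
    """Malformed input file."""


class FixtureError(JunctionSigError):
    """Packaged fixture is missing or corrupted."""


#: IUPAC nucleotide codes and the base sets they stand for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


_SEQ_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class SequenceRegion:
    """A nucleotide sequence with a marked breakpoint.

    The breakpoint lies between 1-based positions ``breakpoint_offset`` and
    ``breakpoint_offset + 1``; equivalently ``seq[:breakpoint_offset]`` is the
    5' side.  The default region used throughout the analysis is 150 bp with
    the breakpoint between nucleotides 75 and 76, matching the convention used
    for the artificial control breakpoints.
    """

    id: str
    seq: str
    breakpoint_offset: int

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("empty sequence")
        bad = set(self.seq) - _SEQ_ALPHABET
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        if not 1 <= self.breakpoint_offset < len(self.seq):
            raise ValueError(
                f"breakpoint_offset {self.breakpoint_offset} outside "
                f"[1, {len(self.seq) - 1}]"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class JunctionCase:
    """One sequenced deletion junction with its two reference flanks.

    ``proximal_ref`` runs from retained 5' sequence into the deleted interval;
    ``distal_ref`` runs from deleted sequence into the retained 3' flank.  The
    junction fragment is the sequenced product joining the two retained sides.
    """

    case_id: str
    proximal_ref: SequenceRegion
    distal_ref: SequenceRegion
    junction: str

    def __post_init__(self) -> None:
        for label, s in (
            ("proximal_ref", self.proximal_ref.seq),
            ("distal_ref", self.distal_ref.seq),
            ("junction", self.junction),
        ):
            if len(s) < 20:
                raise ValueError(f"{label} shorter than 20 nt")
        bad = set(self.junction) - _SEQ_ALPHABET
        if bad:
            raise ValueError(f"non-IUPAC characters in junction: {sorted(bad)}")
        if len(self.junction) > len(self.proximal_ref.seq) + len(self.distal_ref.seq):
            raise ValueError("junction longer than both references combined")


@dataclass(frozen=True)
class DeletionRecord:
    """One row of the bundled deletion-cohort table."""

    patient_code: str
    chrom: str
    start_hg19: int
    end_hg19: int
    mh_len: int
    scar: Optional[str]
    repeat_prox: Optional[str]
    repeat_dist: Optional[str]
    motifs_prox: int
    motifs_dist: int
    nonb_prox: int
    nonb_dist: int
    identity_pct: Optional[int]
    mechanism: str
    deletion_class: str

    def __post_init__(self) -> None:
        if self.end_hg19 <= self.start_hg19:
            raise ValueError("end_hg19 must exceed start_hg19")
        if self.mh_len < 0:
            raise ValueError("mh_len must be >= 0")
        regulatory = self.patient_code.isalpha()
        if (self.deletion_class == "regulatory") != regulatory:
            raise ValueError(
                "deletion_class must be 'regulatory' iff patient_code is alphabetic"
            )


#: Superfamily buckets used for same-family repeat comparisons.
REPEAT_FAMILIES = ("Alu", "L1", "MIR", "LTR", "DNA", "Other")

_DNA_PREFIXES = ("Tigger", "Charlie", "Mer", "MER")
_LTR_PREFIXES = ("LTR", "MLT", "THE")


def repeat_family(name: str) -> str:
    """Map a repeat name to its superfamily bucket.

    AluY -> Alu, L1PA3 -> L1, MIRb -> MIR, LTR33A/MLT1/THE1 -> LTR,
    Tigger/Charlie/Mer DNA transposons -> DNA, anything else -> Other.
    """
    if name.startswith("Alu"):
        return "Alu"
    if name.startswith("L1"):
        return "L1"
    if name.startswith("MIR"):
        return "MIR"
    if name.startswith(_LTR_PREFIXES):
        return "LTR"
    if name.startswith(_DNA_PREFIXES):
        return "DNA"
    return "Other"


@dataclass(frozen=True)
class RepeatFeature:
    """An interspersed-repeat annotation (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    name: str
    family: str
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("repeat interval must have end > start")
        if self.family not in REPEAT_FAMILIES:
            raise ValueError(f"unknown repeat family {self.family!r}")

    def contains(self, pos_1based: int) -> bool:
        return self.start < pos_1based <= self.end


@dataclass(frozen=True)
class MotifDef:
    """A sequence motif as an IUPAC pattern."""

    motif_id: str
    name: str
    pattern: str
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        bad = set(self.pattern) - set(IUPAC_CODES)
        if bad:
            raise ValueError(f"invalid IUPAC codes in pattern: {sorted(bad)}")


# ---------------------------------------------------------------------------
# FASTA

_BP_RE = re.compile(r"\bbp=(\d+)\b")


def read_fasta(path: str | Path) -> list[SequenceRegion]:
    """Read FASTA records as :class:`SequenceRegion`.

    The breakpoint offset defaults to ``len(seq) // 2`` and can be overridden
    with a ``bp=K`` token in the header description.
    """
    path = Path(path)
    regions: list[SequenceRegion] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters "
                f"{sorted(bad)}"
            )
        m = _BP_RE.search(rec.description)
        offset = int(m.group(1)) if m else len(seq) // 2
        regions.append(SequenceRegion(id=rec.id, seq=seq, breakpoint_offset=offset))
    return regions


def write_fasta(regions: Iterable[SequenceRegion], path: str | Path) -> None:
    """Write regions as FASTA, encoding the breakpoint as ``bp=K``."""
    records = [
        SeqRecord(Seq(r.seq), id=r.id, description=f"bp={r.breakpoint_offset}")
        for r in regions
    ]
    SeqIO.write(records, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Repeat annotations: RepeatMasker .out and BED6

def _parse_rm_out_line(fields: list[str]) -> RepeatFeature:
    # standard .out columns: score div del ins query qbegin qend qleft strand
    # repeat class/family rbegin rend rleft id
    chrom = fields[4]
    start = int(fields[5]) - 1  # .out coordinates are 1-based inclusive
    end = int(fields[6])
    strand = "-" if fields[8] in ("C", "-") else "+"
    name = fields[9]
    return RepeatFeature(
        chrom=chrom, start=start, end=end, name=name,
        family=repeat_family(name), strand=strand,
    )


def _parse_bed6_line(fields: list[str]) -> RepeatFeature:
    chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5] if len(fields) >= 6 else "+"
    return RepeatFeature(
        chrom=chrom, start=start, end=end, name=name,
        family=repeat_family(name), strand=strand,
    )


def read_repeatmasker_out(path: str | Path) -> list[RepeatFeature]:
    """Read repeat annotations from RepeatMasker ``.out`` or BED6.

    The format is auto-detected: ``.out`` files carry three header lines and
    >= 14 whitespace-separated columns; BED has tab-separated columns with the
    repeat name in column 4.  Coordinates are normalised to 0-based half-open.
    """
    path = Path(path)
    features: list[RepeatFeature] = []
    with open(path) as fh:
        lines = fh.readlines()
    is_out = bool(lines) and (
        lines[0].lstrip().startswith(("SW", "score")) or len(lines[0].split()) >= 14
    )
    body = lines[3:] if is_out and len(lines) >= 3 else lines
    if not is_out:
        body = lines
    for lineno, line in enumerate(body, start=(4 if is_out else 1)):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        try:
            if is_out:
                features.append(_parse_rm_out_line(fields))
            else:
                features.append(_parse_bed6_line(fields))
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: unparseable line {lineno}: {line!r}") from exc
    return features


def write_repeatmasker_out(features: Iterable[RepeatFeature], path: str | Path) -> None:
    """Write annotations in a minimal RepeatMasker ``.out`` layout."""
    with open(path, "w") as fh:
        fh.write(
            "   SW  perc perc perc  query      position in query           "
            "matching       repeat              position in  repeat\n"
            "score  div. del. ins.  sequence    begin     end    (left)    "
            "repeat         class/family         begin  end (left)   ID\n\n"
        )
        for i, f in enumerate(features, start=1):
            strand = "C" if f.strand == "-" else "+"
            fh.write(
                f"  225  10.0  0.0  0.0  {f.chrom} {f.start + 1} {f.end} (0) "
                f"{strand} {f.name} {f.family}/{f.family} 1 {f.end - f.start} (0) {i}\n"
            )


# ---------------------------------------------------------------------------
# Packaged fixtures

TABLE1_SHA256 = "12cbdca6f015349b74bff6ebb315ca1847609e3df37fb9914cf067af10aa9414"


def _data_path(name: str) -> Path:
    return Path(resources.files("junctionsig").joinpath("data", name))  # type: ignore[arg-type]


def _opt_str(token: str) -> Optional[str]:
    return None if token == "-" else token


def _opt_int(token: str) -> int:
    return 0 if token == "-" else int(token)


def load_table1_fixture() -> list[DeletionRecord]:
    """Load the packaged 24-deletion cohort table.

    Returns 8 regulatory (A-H) and 16 gene-encompassing (1-16) records.  A
    checksum guard rejects silently modified fixture files; microhomology "-"
    rows (perfect transitions) are encoded as ``mh_len = 0``.
    """
    path = _data_path("table1.tsv")
    raw = path.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixtureError(
            f"fixture checksum mismatch for {path.name}: {digest} != {TABLE1_SHA256}"
        )
    records: list[DeletionRecord] = []
    lines = raw.decode().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        code = row["patient_code"]
        rec = DeletionRecord(
            patient_code=code,
            chrom="3",
            start_hg19=int(row["start_hg19"]),
            end_hg19=int(row["end_hg19"]),
            mh_len=_opt_int(row["mh_len"]),
            scar=_opt_str(row["scar"]),
            repeat_prox=_opt_str(row["repeat_prox"]),
            repeat_dist=_opt_str(row["repeat_dist"]),
            motifs_prox=_opt_int(row["motifs_prox"]),
            motifs_dist=_opt_int(row["motifs_dist"]),
            nonb_prox=_opt_int(row["nonb_prox"]),
            nonb_dist=_opt_int(row["nonb_dist"]),
            identity_pct=(None if row["identity_pct"] == "-"
                          else int(row["identity_pct"])),
            mechanism=row["mechanism"],
            deletion_class=("regulatory" if code.isalpha()
                            else "foxl2_encompassing"),
        )
        size_kb = int(row["size_kb"])
        got_kb = int((rec.end_hg19 - rec.start_hg19) / 1000 + 0.5)
        if got_kb != size_kb:
            raise FixtureError(
                f"fixture row {code}: size {got_kb} kb from coordinates does not "
                f"match stored {size_kb} kb"
            )
        records.append(rec)
    if len(records) != 24:
        raise FixtureError(f"expected 24 fixture records, found {len(records)}")
    return records


def load_motif_catalogue(path: str | Path | None = None) -> list[MotifDef]:
    """Load the motif catalogue TSV (the packaged default when no path given).

    The default catalogue bundles 40 rearrangement-associated motifs (chi-like
    elements, translin targets, Ig class-switch repeats, topoisomerase
    cleavage consensi, polymerase pause and frameshift hotspots, V(D)J signal
    sequences, purine/pyrimidine and alternating tracts, and common repeat
    cores).  Any TSV with columns motif_id/name/pattern/both_strands can be
    substituted.
    """
    p = _data_path("motifs.tsv") if path is None else Path(path)
    defs: list[MotifDef] = []
    lines = p.read_text().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        row = dict(zip(header, line.split("\t")))
        defs.append(
            MotifDef(
                motif_id=row["motif_id"],
                name=row["name"],
                pattern=row["pattern"].upper(),
                search_both_strands=row["both_strands"] == "1",
            )
        )
    return defs
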