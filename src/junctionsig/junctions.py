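"""Microhomology, insertion, and information-scar calling at deletion junctions.

Microhomology (MH) is a stretch of perfectly matching sequence shared between
the proximal and distal reference flanks at a deletion junction, such that the
junction fragment aligns equally well to both references across the switch
point.  Its length discriminates candidate repair mechanisms: blunt junctions
(0 bp) point to NHEJ, 1-4 bp is compatible with NHEJ, and >= 5 bp with MMEJ or
replicative template-switch mechanisms.

The caller operationalises MH as two-sided extension at the mapped breakpoints:
starting from the breakpoint of each reference flank, count how far the two
references agree walking left and walking right.  Left-extension covers bases
assigned to the proximal flank that also match the distal reference; right-
extension covers distal-assigned bases that also match the proximal reference.
The observed junction is then compared with the junction expected from the
mapped breakpoints; small deviations near the switch point are emitted as
information scars (substitutions, 1-bp deletions) or as an untemplated
insertion.  N bases never match anything.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_model import DeletionRecord, JunctionCase, JunctionSigError

#: Scars are only recognised this close to the switch point; further-out
#: disagreement makes the junction unmappable.
SCAR_WINDOW = 10

#: Minimum exactly matching bases anchoring the junction to each flank.
MIN_ANCHOR = 10


class JunctionParseError(JunctionSigError):
    """The junction cannot be explained by the two reference flanks."""


@dataclass(frozen=True)
class ScarEvent:
    """A small residual edit at the junction (an "information scar")."""

    kind: str  # substitution | deletion | insertion
    offset: int  # position relative to the switch point (negative = 5')
    ref_allele: str
    alt_allele: str

    def __str__(self) -> str:
        if self.kind == "deletion":
            return f"del({self.ref_allele})"
        if self.kind == "insertion":
            return f"ins({self.alt_allele})"
        return f"{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class MicrohomologyCall:
    """Result of parsing one junction."""

    mh_len: int
    inserted_seq: str
    scar_events: tuple[ScarEvent, ...]
    proximal_bp: int  # refined 1-based position within the proximal reference
    distal_bp: int  # refined 1-based position within the distal reference
    blunt: bool
    left_ext: int = 0  # MH bases 5' of the breakpoint
    right_ext: int = 0  # MH bases 3' of the breakpoint

    def __post_init__(self) -> None:
        if self.mh_len < 0:
            raise ValueError("mh_len must be >= 0")
        if self.blunt and self.inserted_seq:
            raise ValueError("blunt junction cannot carry an insertion")
        if self.inserted_seq and self.mh_len != 0:
            raise ValueError("insertion implies mh_len = 0")


def _match(a: str, b: str) -> bool:
    # N is treated conservatively: it never matches anything.
    return a == b and a != "N"


def two_sided_extension(prox_seq: str, prox_off: int,
                        dist_seq: str, dist_off: int) -> tuple[int, int]:
    """Count matching bases walking out from the two breakpoints.

    Returns ``(left, right)``: the number of bases immediately 5' of both
    breakpoints on which the references agree, and likewise 3'.  Offsets count
    bases on the 5' side of each breakpoint (the breakpoint sits between
    0-based indices ``off - 1`` and ``off``).
    """
    left = 0
    while (left < prox_off and left < dist_off
           and _match(prox_seq[prox_off - 1 - left], dist_seq[dist_off - 1 - left])):
        left += 1
    right = 0
    while (prox_off + right < len(prox_seq) and dist_off + right < len(dist_seq)
           and _match(prox_seq[prox_off + right], dist_seq[dist_off + right])):
        right += 1
    return left, right


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def call_microhomology(case: JunctionCase,
                       max_scar_mismatches: int = 2) -> MicrohomologyCall:
    """Parse a junction into microhomology, insertion, and scar events.

    The MH length is the two-sided extension of reference agreement at the
    mapped breakpoints.  The observed junction is compared against the
    junction expected from the mapped breakpoints; up to
    ``max_scar_mismatches`` isolated substitutions or 1-bp deletions within
    ``SCAR_WINDOW`` bases of the switch point are reported as scar events, and
    an unexplained novel segment at the switch point is reported as an
    insertion (which forces ``mh_len = 0``).  Among equal-MH parses the
    leftmost switch point is reported, so refined breakpoints flank the MH
    stretch on its 5' side.
    """
    prox, dist = case.proximal_ref, case.distal_ref
    p, d = prox.breakpoint_offset, dist.breakpoint_offset
    left, right = two_sided_extension(prox.seq, p, dist.seq, d)
    mh = left + right

    expected = prox.seq[:p] + dist.seq[d:]
    junction = case.junction

    a = _lcp(junction, expected)
    b = _lcs(junction, expected)
    if a < MIN_ANCHOR or b < MIN_ANCHOR:
        raise JunctionParseError(
            f"unmappable junction {case.case_id!r}: anchors of {a} and {b} "
            f"exactly matching bases (need >= {MIN_ANCHOR} each side)"
        )
    # Clip so prefix and suffix anchors do not overlap on either string.
    b = min(b, len(junction) - a, len(expected) - a)

    gap_j = junction[a:len(junction) - b]
    gap_e = expected[a:len(expected) - b]

    scars: list[ScarEvent] = []
    inserted = ""
    if gap_j == gap_e:
        pass  # junction exactly as expected (both gaps empty)
    elif not gap_j and len(gap_e) <= max_scar_mismatches:
        # bases present in the references but absent from the junction
        for i, base in enumerate(gap_e):
            scars.append(ScarEvent("deletion", a + i - p, base, ""))
    elif not gap_e:
        if mh != 0:
            raise JunctionParseError(
                f"junction {case.case_id!r} implies both an insertion "
                f"({gap_j!r}) and microhomology ({mh} bp)"
            )
        inserted = gap_j
    elif len(gap_j) == len(gap_e) and len(gap_j) <= max_scar_mismatches:
        for i, (ref, alt) in enumerate(zip(gap_e, gap_j)):
            scars.append(ScarEvent("substitution", a + i - p, ref, alt))
    else:
        raise JunctionParseError(
            f"unmappable junction {case.case_id!r}: cannot explain "
            f"{gap_e!r} -> {gap_j!r} with <= {max_scar_mismatches} scar events"
        )

    if len(scars) > max_scar_mismatches:
        raise JunctionParseError(
            f"junction {case.case_id!r}: {len(scars)} scar events exceed "
            f"limit {max_scar_mismatches}"
        )
    for ev in scars:
        if abs(ev.offset) > SCAR_WINDOW:
            raise JunctionParseError(
                f"junction {case.case_id!r}: scar at offset {ev.offset} "
                f"outside the {SCAR_WINDOW}-bp window around the switch point"
            )

    blunt = mh == 0 and not inserted
    # Breakpoints flank the MH stretch: last base 5' of the stretch on the
    # proximal reference, first base 3' of it on the distal reference.
    proximal_bp = p - left
    distal_bp = d + right + 1
    return MicrohomologyCall(
        mh_len=mh,
        inserted_seq=inserted,
        scar_events=tuple(scars),
        proximal_bp=proximal_bp,
        distal_bp=distal_bp,
        blunt=blunt,
        left_ext=left,
        right_ext=right,
    )


def locate_breakpoints(call: MicrohomologyCall,
                       case: JunctionCase) -> tuple[int, int]:
    """Refined breakpoints: the positions flanking the MH stretch.

    The proximal breakpoint is the last nucleotide 5'-adjacent to the MH
    stretch in the proximal reference; the distal breakpoint is the first
    nucleotide 3'-adjacent to it in the distal reference.  For a blunt
    junction the two positions flank the switch point directly.  Positions are
    1-based within each reference region.
    """
    return call.proximal_bp, call.distal_bp


def deletion_size(rec: DeletionRecord) -> tuple[int, int]:
    """Deletion size in bp and rounded kb (half-up), from the coordinates."""
    bp = rec.end_hg19 - rec.start_hg19
    if bp <= 0:
        raise ValueError("non-positive deletion size")
    return bp, int(bp / 1000 + 0.5)
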