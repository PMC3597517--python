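"""Scanners for the genomic architecture of 150-bp breakpoint regions.

Each breakpoint of a deletion is examined in a 150-bp window centred on the
breakpoint (75 nt each side).  Three classes of architectural features are
scanned for, all implicated in DNA breakage or replication-fork stalling:

* sequence motifs from an IUPAC-pattern catalogue (rearrangement-associated
  elements such as chi-like sequences, translin targets, topoisomerase
  cleavage sites);
* sequences capable of adopting non-B DNA conformations: direct, inverted and
  mirror repeats (slipped hairpin, cruciform and triplex structures),
  oligo(G) tracts (tetraplex), and alternating purine-pyrimidine tracts
  (left-handed Z-DNA);
* annotated interspersed repeats (Alu, L1, ...) intersecting the breakpoint
  itself, with pairwise identity between repeats flanking both breakpoints of
  a deletion as NAHR supporting evidence.

Non-B features only count when they flank the breakpoint: a two-armed repeat
must place one arm on each side of the breakpoint (or overlap it), a single
tract must overlap it.

The tetraplex detector is a documented surrogate for QGRS-style mapping:
candidate quadruplexes are built from maximal G-runs, scored by
``20*(x - 2) + (max_span - span) - sum of pairwise loop-length differences``
where ``x`` is the shortest of the four G-runs.  Longer runs and more even
loops score higher.  The Z-DNA detector is likewise a surrogate for
statistical-mechanical scoring: maximal alternating purine-pyrimidine tracts
built from GT/GC/AC dinucleotide steps, of length >= 12.  Both are applied
identically to observed and control regions, so enrichment comparisons remain
internally consistent.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from Bio import Align

from .io_model import (
    IUPAC_CODES,
    MotifDef,
    RepeatFeature,
    SequenceRegion,
    revcomp,
)

DEFAULT_MIN_ARM = 8
DEFAULT_MAX_SPACER = 120
DEFAULT_G4_MIN_RUN = 2
DEFAULT_G4_MAX_SPAN = 30
DEFAULT_ZDNA_MIN_LEN = 12

#: Arms made of fewer than two effective bases (entropy <= 1 bit) are
#: suppressed: homopolymers and plain dinucleotide repeats otherwise flood
#: the repeat scanners with trivially dense calls.
ARM_ENTROPY_MIN_BITS = 1.0


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    strand: str


@dataclass(frozen=True)
class NonBFeature:
    """A sequence capable of forming a non-B DNA conformation."""

    kind: str  # direct_repeat | inverted_repeat | mirror_repeat | tetraplex | zdna
    arm1: tuple[int, int]
    arm2: Optional[tuple[int, int]]
    score: float
    flanks_breakpoint: bool


@dataclass(frozen=True)
class ArchitectureProfile:
    """Architecture summary of one breakpoint region."""

    region_id: str
    repeat_at_breakpoint: Optional[RepeatFeature]
    motif_hits: tuple[MotifHit, ...]
    nonb_features: tuple[NonBFeature, ...]

    @property
    def motif_count(self) -> int:
        return len(self.motif_hits)

    @property
    def nonb_count(self) -> int:
        return len(self.nonb_features)


# ---------------------------------------------------------------------------
# Motif scanning

def _iupac_regex(pattern: str) -> re.Pattern[str]:
    parts = []
    for code in pattern:
        bases = IUPAC_CODES[code]
        parts.append(next(iter(bases)) if len(bases) == 1
                     else "[" + "".join(sorted(bases)) + "]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_motifs(region: SequenceRegion,
                catalogue: Sequence[MotifDef]) -> list[MotifHit]:
    """All occurrences of every catalogue motif in the region.

    Overlapping occurrences are reported; motifs flagged for both strands are
    additionally scanned on the reverse complement, with hits mapped back to
    forward-strand coordinates.  Hits are sorted by start, then motif id.
    """
    if not catalogue:
        raise ValueError("empty motif catalogue")
    seq = region.seq
    n = len(seq)
    hits: list[MotifHit] = []
    for mdef in catalogue:
        rx = _iupac_regex(mdef.pattern)
        plen = len(mdef.pattern)
        for m in rx.finditer(seq):
            hits.append(MotifHit(mdef.motif_id, m.start(), m.start() + plen, "+"))
        if mdef.search_both_strands:
            rc = revcomp(seq)
            for m in rx.finditer(rc):
                s = n - (m.start() + plen)
                hits.append(MotifHit(mdef.motif_id, s, s + plen, "-"))
    hits.sort(key=lambda h: (h.start, h.motif_id, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Direct / inverted / mirror repeats

def _entropy_bits(s: str) -> float:
    n = len(s)
    h = 0.0
    for b in set(s):
        p = s.count(b) / n
        h -= p * math.log2(p)
    return h


def _flanks(arm1: tuple[int, int], arm2: Optional[tuple[int, int]],
            off: int) -> bool:
    """Breakpoint-flanking rule (breakpoint between 0-based off-1 and off)."""
    def overlaps(iv: tuple[int, int]) -> bool:
        return iv[0] < off < iv[1]

    if arm2 is None:
        return overlaps(arm1)
    if overlaps(arm1) or overlaps(arm2):
        return True
    return arm1[1] <= off and arm2[0] >= off


def _base_match(a: str, b: str) -> bool:
    return a == b and a != "N"


def _runs(mask: list[bool]) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    out = []
    i, n = 0, len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def find_direct_repeats(region: SequenceRegion,
                        min_arm: int = DEFAULT_MIN_ARM,
                        max_spacer: int = DEFAULT_MAX_SPACER) -> list[NonBFeature]:
    """Maximal pairs of identical substrings (slipped-hairpin substrates).

    For every arm separation the maximal identical runs are located; a run of
    length r at separation d yields a feature with arm length min(r, d) (runs
    longer than the separation are tandem arrays, reported once).  Arms must
    not overlap, the spacer must not exceed ``max_spacer``, and arms with
    base-composition entropy <= 1 bit are suppressed.
    """
    if min_arm < 8:
        raise ValueError("min_arm must be >= 8")
    seq = region.seq
    n = len(seq)
    off = region.breakpoint_offset
    feats: list[NonBFeature] = []
    for d in range(1, n):
        mask = [_base_match(seq[k], seq[k + d]) for k in range(n - d)]
        for start, r in _runs(mask):
            t = min(r, d)
            if t < min_arm:
                continue
            spacer = d - t
            if spacer > max_spacer:
                continue
            arm1 = (start, start + t)
            arm2 = (start + d, start + d + t)
            if _entropy_bits(seq[arm1[0]:arm1[1]]) <= ARM_ENTROPY_MIN_BITS:
                continue
            feats.append(NonBFeature("direct_repeat", arm1, arm2, float(t),
                                     _flanks(arm1, arm2, off)))
    feats.sort(key=lambda f: (f.arm1, f.arm2 or (0, 0)))
    return feats


def _antidiagonal_repeats(region: SequenceRegion, kind: str, min_arm: int,
                          max_spacer: int, complement: bool) -> list[NonBFeature]:
    # An inverted (mirror) repeat pairs positions u < v with u + v constant,
    # where s[v] must equal the complement of s[u] (s[u] itself for mirror).
    seq = region.seq
    n = len(seq)
    off = region.breakpoint_offset
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    feats: list[NonBFeature] = []
    for m in range(1, 2 * n - 2):
        u_hi = (m - 1) // 2  # largest u with u < m - u
        u_lo = max(0, m - n + 1)
        if u_hi < u_lo:
            continue
        mask = []
        for u in range(u_lo, u_hi + 1):
            v = m - u
            a, b = seq[u], seq[v]
            if complement:
                ok = a != "N" and b != "N" and comp.get(a) == b
            else:
                ok = _base_match(a, b)
            mask.append(ok)
        for start, r in _runs(mask):
            a0 = u_lo + start
            b0 = a0 + r  # arm1 = [a0, b0)
            if r < min_arm:
                continue
            arm1 = (a0, b0)
            arm2 = (m - b0 + 1, m - a0 + 1)
            spacer = arm2[0] - arm1[1]
            if spacer > max_spacer:
                continue
            if _entropy_bits(seq[arm1[0]:arm1[1]]) <= ARM_ENTROPY_MIN_BITS:
                continue
            feats.append(NonBFeature(kind, arm1, arm2, float(r),
                                     _flanks(arm1, arm2, off)))
    feats.sort(key=lambda f: (f.arm1, f.arm2 or (0, 0)))
    return feats


def find_inverted_repeats(region: SequenceRegion,
                          min_arm: int = DEFAULT_MIN_ARM,
                          max_spacer: int = DEFAULT_MAX_SPACER) -> list[NonBFeature]:
    """Maximal arm pairs where arm2 is the reverse complement of arm1
    (cruciform substrates)."""
    if min_arm < 8:
        raise ValueError("min_arm must be >= 8")
    return _antidiagonal_repeats(region, "inverted_repeat", min_arm,
                                 max_spacer, complement=True)


def find_mirror_repeats(region: SequenceRegion,
                        min_arm: int = DEFAULT_MIN_ARM,
                        max_spacer: int = DEFAULT_MAX_SPACER) -> list[NonBFeature]:
    """Maximal arm pairs where arm2 is the reverse of arm1 (triplex
    substrates)."""
    if min_arm < 8:
        raise ValueError("min_arm must be >= 8")
    return _antidiagonal_repeats(region, "mirror_repeat", min_arm,
                                 max_spacer, complement=False)


# ---------------------------------------------------------------------------
# Tetraplex (G4) and Z-DNA

def g4_score(run_len: int, loops: tuple[int, int, int],
             max_span: int = DEFAULT_G4_MAX_SPAN) -> float:
    """G-score of a quadruplex candidate (see module docstring)."""
    a, b, c = loops
    span = 4 * run_len + a + b + c  # span when all runs have length run_len
    return 20.0 * (run_len - 2) + (max_span - span) \
        - (abs(a - b) + abs(a - c) + abs(b - c))


def _g_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer("G{%d,}" % min_run, seq)]


def find_tetraplex(region: SequenceRegion,
                   min_run: int = DEFAULT_G4_MIN_RUN,
                   max_span: int = DEFAULT_G4_MAX_SPAN) -> list[NonBFeature]:
    """Oligo(G)-tract quadruplex candidates.

    Candidates are all choices of four maximal G-runs (each >= ``min_run``
    Gs, separated by >= 1 non-G base) whose total span does not exceed
    ``max_span``.  The shortest of the four runs sets the tetrad size; the
    G-score rewards longer runs, compact span, and even loops.  Overlapping
    candidates are reduced to the highest-scoring one per locus.
    """
    seq = region.seq
    off = region.breakpoint_offset
    runs = _g_runs(seq, min_run)
    candidates: list[tuple[float, tuple[int, int]]] = []
    for quad in combinations(range(len(runs)), 4):
        s = runs[quad[0]][0]
        e = runs[quad[3]][1]
        if e - s > max_span:
            continue
        x = min(runs[i][1] - runs[i][0] for i in quad)
        loops = tuple(runs[quad[i + 1]][0] - runs[quad[i]][1] for i in range(3))
        # effective span uses x Gs per run: trailing G excess does not count
        span = 4 * x + sum(loops)
        if span > max_span:
            continue
        candidates.append((g4_score(x, loops, max_span), (s, e)))
    candidates.sort(key=lambda c: (-c[0], c[1]))
    chosen: list[tuple[float, tuple[int, int]]] = []
    for score, iv in candidates:
        if all(iv[1] <= c[1][0] or iv[0] >= c[1][1] for c in chosen):
            chosen.append((score, iv))
    chosen.sort(key=lambda c: c[1])
    return [NonBFeature("tetraplex", iv, None, score, _flanks(iv, None, off))
            for score, iv in chosen]


_Z_STEPS = frozenset({frozenset("GT"), frozenset("GC"), frozenset("AC")})


def find_zdna(region: SequenceRegion,
              min_len: int = DEFAULT_ZDNA_MIN_LEN) -> list[NonBFeature]:
    """Maximal alternating purine-pyrimidine tracts (Z-DNA substrates).

    Tracts are built from GT, GC and AC dinucleotide steps (in either order);
    AT and AG steps break a tract.  Only tracts of ``min_len`` or more bases
    are reported, scored by their length.
    """
    seq = region.seq
    off = region.breakpoint_offset
    n = len(seq)
    feats: list[NonBFeature] = []
    i = 0
    while i < n - 1:
        if frozenset(seq[i:i + 2]) in _Z_STEPS:
            j = i + 1
            while j < n - 1 and frozenset(seq[j:j + 2]) in _Z_STEPS:
                j += 1
            length = j - i + 1
            if length >= min_len:
                iv = (i, j + 1)
                feats.append(NonBFeature("zdna", iv, None, float(length),
                                         _flanks(iv, None, off)))
            i = j + 1
        else:
            i += 1
    return feats


def filter_flanking(features: Sequence[NonBFeature],
                    region: SequenceRegion) -> list[NonBFeature]:
    """Keep only features whose counterparts flank (or overlap) the breakpoint.

    Never increases the feature count; the flag itself is assigned by the
    scanners from the region's breakpoint offset.
    """
    return [f for f in features if f.flanks_breakpoint]


# ---------------------------------------------------------------------------
# Repeat intersection and identity

def repeat_at_breakpoint(bp_position: int,
                         features: Sequence[RepeatFeature],
                         region_halfwidth: int = 75) -> Optional[RepeatFeature]:
    """The annotated repeat containing a (1-based) breakpoint position.

    Ties are broken by the longest overlap with the 150-bp breakpoint region,
    then by coordinate.
    """
    window = (bp_position - region_halfwidth, bp_position + region_halfwidth)
    hits = [f for f in features if f.contains(bp_position)]
    if not hits:
        return None

    def overlap(f: RepeatFeature) -> int:
        return max(0, min(f.end, window[1]) - max(f.start, window[0]))

    hits.sort(key=lambda f: (-overlap(f), f.start))
    return hits[0]


def pairwise_identity(seq_a: str, seq_b: str) -> int:
    """Percent identity from a global alignment of two sequences.

    Scoring: match +1, mismatch -2, gap open -5, gap extend -2.  Identity is
    100 * matches / alignment columns, rounded to the nearest integer —
    the convention used for reporting identity between repeat elements
    flanking the two breakpoints of a deletion.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if not (50 <= len(seq_a) <= 10_000 and 50 <= len(seq_b) <= 10_000):
        raise ValueError("sequences must be 50-10000 nt")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = aln.length
    return int(100 * counts.identities / columns + 0.5)


# ---------------------------------------------------------------------------
# Profiles

def build_profile(region: SequenceRegion,
                  catalogue: Sequence[MotifDef],
                  repeats: Sequence[RepeatFeature] = (),
                  bp_genomic: Optional[int] = None,
                  min_arm: int = DEFAULT_MIN_ARM,
                  max_spacer: int = DEFAULT_MAX_SPACER) -> ArchitectureProfile:
    """Full architecture profile of one breakpoint region.

    Motif hits are counted per occurrence; non-B features are restricted to
    those flanking/overlapping the breakpoint, matching how the per-region
    counts in the cohort table were defined.
    """
    motif_hits = scan_motifs(region, catalogue)
    nonb: list[NonBFeature] = []
    nonb += find_direct_repeats(region, min_arm, max_spacer)
    nonb += find_inverted_repeats(region, min_arm, max_spacer)
    nonb += find_mirror_repeats(region, min_arm, max_spacer)
    nonb += find_tetraplex(region)
    nonb += find_zdna(region)
    nonb = filter_flanking(nonb, region)
    rep = None
    if bp_genomic is not None and repeats:
        rep = repeat_at_breakpoint(bp_genomic, repeats)
    return ArchitectureProfile(
        region_id=region.id,
        repeat_at_breakpoint=rep,
        motif_hits=tuple(motif_hits),
        nonb_features=tuple(nonb),
    )
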