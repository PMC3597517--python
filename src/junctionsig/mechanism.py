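"""Repair-mechanism classification from breakpoint-junction signatures.

Deletions are sorted into three groups by their junction signature:

* group 1 — perfect transition (no microhomology): classic NHEJ, possibly
  with an information scar such as a 1-bp deletion;
* group 2 — microhomology plus repeat elements of the same superfamily at
  both breakpoints: NAHR is a candidate alongside replicative template-switch
  mechanisms (FoSTeS/MMBIR/SRS/BISRS, collectively "Replicative") and, for
  MH >= 5 bp, MMEJ;
* group 3 — microhomology without a same-superfamily repeat pair:
  replicative mechanisms, with MMEJ (MH >= 5 bp) or NHEJ (MH 1-4 bp) as the
  end-joining alternative.

NAHR is never the sole call; it requires near-identity over a minimal
efficient processing segment (MEPS), so high pairwise identity between the
flanking repeats is noted as supporting evidence rather than proof.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .io_model import DeletionRecord, repeat_family

#: Microhomology length (bp) at and above which MMEJ replaces NHEJ as the
#: compatible end-joining mechanism.
MMEJ_MIN_MH = 5

#: Pairwise identity (percent) treated as MEPS-compatible for NAHR.
MEPS_IDENTITY = 90


@dataclass(frozen=True)
class MechanismCall:
    """Classification of one deletion."""

    group: int
    candidates: tuple[str, ...]
    rationale: str

    def __post_init__(self) -> None:
        if self.group not in (1, 2, 3):
            raise ValueError("group must be 1, 2 or 3")
        if self.group == 1 and self.candidates != ("NHEJ",):
            raise ValueError("group 1 must call NHEJ alone")
        if "NAHR" in self.candidates and self.group != 2:
            raise ValueError("NAHR calls belong to group 2")
        if self.group == 3 and self.candidates not in (
            ("Replicative", "NHEJ"), ("Replicative", "MMEJ"),
        ):
            raise ValueError("group 3 must call Replicative with NHEJ or MMEJ")

    def mechanism_string(self) -> str:
        return "/".join(self.candidates)


def classify_mechanism(mh_len: int,
                       scar_present: bool,
                       repeat_prox_family: Optional[str],
                       repeat_dist_family: Optional[str],
                       identity_pct: Optional[float] = None) -> MechanismCall:
    """Classify one deletion from its junction signature.

    ``repeat_*_family`` are superfamily buckets (Alu, L1, MIR, LTR, DNA,
    Other) or None when no repeat intersects that breakpoint.  Same-family
    means the same bucket: AluJo/AluSz count as a pair, L1PA4/MIRb do not.
    """
    if mh_len < 0:
        raise ValueError("mh_len must be >= 0")

    notes: list[str] = []
    if mh_len == 0:
        if scar_present:
            notes.append("perfect transition with an information scar")
        else:
            notes.append("perfect transition at the junction")
        return MechanismCall(1, ("NHEJ",), "; ".join(notes))

    same_family = (
        repeat_prox_family is not None
        and repeat_prox_family == repeat_dist_family
    )
    ej = "MMEJ" if mh_len >= MMEJ_MIN_MH else "NHEJ"
    notes.append(f"{mh_len} bp microhomology ({ej}-compatible)")

    if same_family:
        notes.append(
            f"{repeat_prox_family} elements at both breakpoints (NAHR candidate)"
        )
        if identity_pct is not None:
            if identity_pct >= MEPS_IDENTITY:
                notes.append(
                    f"repeat identity {identity_pct:.0f}% (MEPS-compatible)"
                )
            else:
                notes.append(f"repeat identity {identity_pct:.0f}%")
        if ej == "NHEJ":
            # Same-family repeats with 1-4 bp MH do not occur in the cohort;
            # the call extends the MH-length rule and is flagged as such.
            notes.append("short-MH/NAHR combination (extrapolated rule)")
        return MechanismCall(2, ("NAHR", "Replicative", ej), "; ".join(notes))

    return MechanismCall(3, ("Replicative", ej), "; ".join(notes))


def classify_all(records: Sequence[DeletionRecord],
                 ) -> tuple[list[MechanismCall], dict[int, int]]:
    """Classify every cohort record; returns calls plus per-group counts."""
    calls: list[MechanismCall] = []
    for rec in records:
        fam_p = repeat_family(rec.repeat_prox) if rec.repeat_prox else None
        fam_d = repeat_family(rec.repeat_dist) if rec.repeat_dist else None
        calls.append(
            classify_mechanism(
                rec.mh_len,
                scar_present=rec.scar is not None,
                repeat_prox_family=fam_p,
                repeat_dist_family=fam_d,
                identity_pct=rec.identity_pct,
            )
        )
    counts = dict(Counter(call.group for call in calls))
    return calls, counts
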