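"""Synthetic locus, repeat annotations, and deletion alleles with known truth.

No raw sequence data are deposited for the deletion cohort this package
analyses, so every pipeline stage is exercised on synthetic data instead: a
random background locus with planted repeat-element decoys stands in for the
reference chromosome and its RepeatMasker track, and deletion alleles are
planted with controlled junction signatures — microhomology length (0-70 bp),
junction scars (1-2 bp substitutions, 1-bp deletions), untemplated inserted
nucleotides, and repeat-element context (same-superfamily, different-family,
one-sided, or repeat-free breakpoints).

Decoy repeats are consensus-derived random cassettes, not real Alu/L1
sequence; per-copy substitution rates control the pairwise identity between
copies (two copies mutated at 15% each diverge to roughly 72-78% identity,
the low end observed between repeat pairs in the cohort; 2% per copy gives
~96%, the high end).  Copies carry no indels, so the generator's own identity
truth is the Hamming identity between the two cassette sequences.

Microhomology is planted by copying the ``mh`` bases immediately 5' of the
proximal breakpoint over the bases immediately 5' of the distal breakpoint,
then forcing a mismatch at both extension boundaries and verifying that no
longer accidental homology parse of the junction exists (the maximal parse of
an insert-free junction has microhomology lcp + lcs - len, so the check is
exact); offending draws are resampled.  Planted signatures are therefore
recovered exactly by the caller, making parameter-recovery tests sharp rather
than probabilistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_model import JunctionCase, RepeatFeature, SequenceRegion, repeat_family
from .mechanism import MechanismCall, classify_mechanism

FLANK = 75  # bases kept on each side of a breakpoint in a region
REGION_LEN = 2 * FLANK

_FAMILY_SPECS = {
    # family bucket -> (cassette name stem, cassette length)
    "Alu": ("AluSim", 300),
    "L1": ("L1Sim", 2000),
    "MIR": ("MIRSim", 200),
    "DNA": ("TiggerSim", 500),
    "LTR": ("LTRSim", 400),
}
_FAMILY_WEIGHTS = {"Alu": 0.45, "L1": 0.35, "MIR": 0.08, "DNA": 0.07, "LTR": 0.05}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class DeletionSpec:
    """Parameters of one planted deletion allele."""

    size_bp: int
    mh_len: int = 0
    insert_seq: str = ""
    scar: Optional[str] = None  # e.g. "TC>AA", "C>A", "del(T)"
    repeat_context: str = "none"
    arm_divergence_pct: float = 0.0
    seed: int = 0
    families: tuple[Optional[str], Optional[str]] = (None, None)

    def __post_init__(self) -> None:
        if not 0 <= self.mh_len <= 70:
            raise ValueError("mh_len must be in 0..70")
        if self.mh_len > 0 and self.insert_seq:
            raise ValueError("inserted sequence requires mh_len = 0")
        if self.size_bp <= self.mh_len + 20:
            raise ValueError("size_bp must exceed mh_len + 20")
        if self.repeat_context not in (
            "none", "same_family_alu", "same_family_l1", "different_family",
            "one_side",
        ):
            raise ValueError(f"unknown repeat_context {self.repeat_context!r}")
        if not 0 <= self.arm_divergence_pct <= 30:
            raise ValueError("arm_divergence_pct must be in 0..30")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one planted deletion."""

    spec: DeletionSpec
    start: int  # 1-based proximal breakpoint (last retained base)
    end: int  # 1-based distal breakpoint (last deleted base)
    family_prox: Optional[str]
    family_dist: Optional[str]
    identity_pct: Optional[int]
    expected_call: MechanismCall


def _rand_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> np.ndarray:
    at, gcw = (1 - gc) / 2, gc / 2
    return rng.choice(4, size=n, p=[at, gcw, gcw, at]).astype(np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a new base)."""
    out = arr.copy()
    hit = rng.random(len(arr)) < rate
    shifts = rng.integers(1, 4, size=int(hit.sum()))
    out[hit] = (out[hit] + shifts) % 4
    return out


def generate_locus(length: int = 200_000,
                   gc: float = 0.41,
                   repeat_density: float = 0.2,
                   seed: int = 0,
                   ) -> tuple[SequenceRegion, list[RepeatFeature]]:
    """A synthetic reference locus with planted repeat cassettes.

    The background is iid sequence at the requested GC; cassette copies of
    per-family random consensi (Alu-like ~300 nt, L1-like ~2 knt, plus
    MIR/DNA-transposon/LTR decoys) are planted without overlap until
    approximately ``repeat_density`` of the locus is covered, each copy
    carrying its own substitution load (2-15%).  Annotations exactly describe
    the planted copies.  Fully reproducible under ``seed``.
    """
    if repeat_density > 0.5:
        raise ValueError("repeat_density above 0.5 is not supported")
    if length < 2_000:
        raise ValueError("locus too short")
    rng = np.random.default_rng(seed)
    locus = _rand_seq(rng, length, gc)
    consensi = {
        fam: _rand_seq(rng, flen, 0.5)
        for fam, (_, flen) in _FAMILY_SPECS.items()
    }
    families = list(_FAMILY_SPECS)
    weights = np.array([_FAMILY_WEIGHTS[f] for f in families])
    weights = weights / weights.sum()
    occupied = np.zeros(length, dtype=bool)
    features: list[RepeatFeature] = []
    planted = 0
    target = int(repeat_density * length)
    counters = {fam: 0 for fam in families}
    attempts = 0
    while planted < target and attempts < 50 * max(target, 1):
        attempts += 1
        fam = families[rng.choice(len(families), p=weights)]
        stem, flen = _FAMILY_SPECS[fam]
        if flen + 200 >= length:
            continue
        start = int(rng.integers(100, length - flen - 100))
        if occupied[start:start + flen].any():
            continue
        rate = float(rng.uniform(0.02, 0.15))
        copy = _mutate(consensi[fam], rate, rng)
        locus[start:start + flen] = copy
        occupied[start:start + flen] = True
        counters[fam] += 1
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            RepeatFeature(
                chrom="chrSim", start=start, end=start + flen,
                name=f"{stem}{counters[fam]}", family=fam, strand=strand,
            )
        )
        planted += flen
    features.sort(key=lambda f: f.start)
    region = SequenceRegion(id="chrSim", seq=_to_str(locus),
                            breakpoint_offset=length // 2)
    return region, features


# ---------------------------------------------------------------------------
# Deletion planting

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


def max_parse_microhomology(case: JunctionCase) -> int:
    """Maximal two-sided microhomology over all parses of a junction.

    For an insert-free junction the maximum over all (split) parses equals
    ``lcp(junction, proximal) + lcs(junction, distal) - len(junction)``; a
    negative value means no split explains the junction without an insert.
    Used by the generator to reject draws with accidental homology exceeding
    the planted length.
    """
    a = _lcp(case.junction, case.proximal_ref.seq)
    b = _lcs(case.junction, case.distal_ref.seq)
    return a + b - len(case.junction)


def _pick_other(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


class _ContextError(Exception):
    pass


def _choose_breakpoints(spec: DeletionSpec,
                        locus_len: int,
                        annotations: Sequence[RepeatFeature],
                        rng: np.random.Generator
                        ) -> tuple[int, int, Optional[RepeatFeature],
                                   Optional[RepeatFeature]]:
    """Pick 0-based breakpoint boundaries (deleted interval [s, e))."""
    ctx = spec.repeat_context
    margin = FLANK + 2

    def inside(f: RepeatFeature) -> int:
        # a breakpoint position strictly inside the cassette, away from edges
        lo, hi = f.start + 10, f.end - 10
        return int(rng.integers(lo, hi))

    by_family: dict[str, list[RepeatFeature]] = {}
    for f in annotations:
        by_family.setdefault(f.family, []).append(f)

    def clear_of_repeats(pos: int) -> bool:
        return all(not f.contains(pos) for f in annotations)

    if ctx == "none":
        for _ in range(200):
            s = int(rng.integers(margin, locus_len - margin - spec.size_bp))
            e = s + spec.size_bp
            if clear_of_repeats(s) and clear_of_repeats(e):
                return s, e, None, None
        raise _ContextError("no repeat-free breakpoint pair found")

    def draw_families() -> tuple[Optional[str], Optional[str]]:
        if ctx in ("same_family_alu", "same_family_l1"):
            fam = "Alu" if ctx.endswith("alu") else "L1"
            return fam, fam
        if ctx == "different_family":
            fams = spec.families
            if fams[0] is not None and fams[1] is not None:
                return fams
            avail = [f for f in by_family if len(by_family[f]) >= 1]
            if len(avail) < 2:
                raise _ContextError("fewer than two repeat families available")
            i, j = rng.choice(len(avail), size=2, replace=False)
            return avail[int(i)], avail[int(j)]
        # one_side
        fams = spec.families
        if fams == (None, None):
            fams = (list(by_family)[0], None)
        return fams

    for _ in range(200):
        fams = draw_families()
        if fams[0] is not None:
            pool = [f for f in by_family.get(fams[0], [])
                    if f.start > margin and f.end < locus_len - margin]
            if not pool:
                raise _ContextError(f"no {fams[0]} cassette available")
            c1 = pool[int(rng.integers(0, len(pool)))]
            s = inside(c1)
        else:
            c1 = None
            s = int(rng.integers(margin, locus_len - margin))
            if not clear_of_repeats(s):
                continue
        if fams[1] is not None:
            same = fams[0] == fams[1]
            pool = [f for f in by_family.get(fams[1], [])
                    if f.start > s + 30 and f.end < locus_len - margin
                    and (not same or c1 is None or f is not c1)]
            if not pool:
                continue
            c2 = pool[int(rng.integers(0, len(pool)))]
            e = inside(c2)
        else:
            c2 = None
            e = int(rng.integers(s + spec.mh_len + 30,
                                 min(locus_len - margin,
                                     s + spec.mh_len + 30 + spec.size_bp)))
            if not clear_of_repeats(e):
                continue
        if e - s <= spec.mh_len + 20:
            continue
        return s, e, c1, c2
    raise _ContextError(f"could not satisfy repeat context {ctx!r}")


def _parse_scar(scar: str) -> tuple[str, str, str]:
    """-> (kind, ref, alt)."""
    if scar.startswith("del(") and scar.endswith(")"):
        return "deletion", scar[4:-1], ""
    if ">" in scar:
        ref, alt = scar.split(">")
        if len(ref) != len(alt) or not 1 <= len(ref) <= 2:
            raise ValueError(f"unsupported scar {scar!r}")
        return "substitution", ref, alt
    raise ValueError(f"unsupported scar {scar!r}")


def plant_deletion(reference: SequenceRegion,
                   spec: DeletionSpec,
                   annotations: Sequence[RepeatFeature] = (),
                   max_resamples: int = 1000,
                   ) -> tuple[JunctionCase, SimTruth]:
    """Plant one deletion allele with the requested junction signature.

    Breakpoints are chosen to honour ``spec.repeat_context``; exactly
    ``spec.mh_len`` bases of shared sequence are enforced immediately 5' of
    both breakpoints by local editing of the distal flank, with mismatches
    forced at both extension boundaries.  Scar and insert edits are applied
    to the emitted junction only.  Draws where the junction admits a longer
    accidental homology parse are resampled, so the planted signature is the
    unique maximal parse.
    """
    locus = reference.seq
    n = len(locus)
    rng = np.random.default_rng(spec.seed)
    last_err: Exception | None = None
    for _ in range(max_resamples):
        try:
            s, e, c1, c2 = _choose_breakpoints(spec, n, annotations, rng)
        except _ContextError as exc:
            raise ValueError(str(exc)) from exc
        prox = list(locus[s - FLANK:s + FLANK])
        dist = list(locus[e - FLANK:e + FLANK])
        mh = spec.mh_len

        cassette_prox = cassette_dist = None
        if c1 is not None:
            cassette_prox = list(locus[c1.start:c1.end])
        if c2 is not None:
            cassette_dist = list(locus[c2.start:c2.end])
        if (spec.arm_divergence_pct > 0 and cassette_prox is not None
                and cassette_dist is not None and c1.family == c2.family):
            # re-derive the distal cassette from the proximal copy at the
            # requested divergence, then refresh the distal window
            src = np.frombuffer("".join(cassette_prox).encode(), dtype="S1")
            idx = np.searchsorted(_BASES, src)
            div = _mutate(idx.astype(np.uint8), spec.arm_divergence_pct / 100,
                          rng)
            cassette_dist = list(_to_str(div))
            for k in range(max(c2.start, e - FLANK), min(c2.end, e + FLANK)):
                dist[k - (e - FLANK)] = cassette_dist[k - c2.start]

        def put_dist(i: int, base: str) -> None:
            dist[i] = base
            if c2 is not None and c2.start <= (e - FLANK) + i < c2.end:
                cassette_dist[(e - FLANK) + i - c2.start] = base

        def put_prox(i: int, base: str) -> None:
            prox[i] = base
            if c1 is not None and c1.start <= (s - FLANK) + i < c1.end:
                cassette_prox[(s - FLANK) + i - c1.start] = base

        # plant the shared stretch 5' of both breakpoints
        for k in range(mh):
            put_dist(FLANK - mh + k, prox[FLANK - mh + k])
        # force mismatches at both extension boundaries
        if dist[FLANK - mh - 1] == prox[FLANK - mh - 1]:
            put_dist(FLANK - mh - 1, _pick_other(rng, prox[FLANK - mh - 1]))
        if dist[FLANK] == prox[FLANK]:
            put_dist(FLANK, _pick_other(rng, prox[FLANK]))

        scar_kind = ref_alleles = alt_alleles = None
        if spec.scar is not None:
            scar_kind, ref_alleles, alt_alleles = _parse_scar(spec.scar)
            if scar_kind == "deletion":
                if mh != 0 or len(ref_alleles) != 1:
                    raise ValueError(
                        "deletion scars are modelled at blunt junctions only")
                put_prox(FLANK - 1, ref_alleles)
                # keep the lost base identifiable on both sides
                if dist[FLANK] == ref_alleles:
                    put_dist(FLANK, _pick_other(rng, ref_alleles))
                if prox[FLANK - 2] == ref_alleles:
                    put_prox(FLANK - 2, _pick_other(rng, ref_alleles,
                                                    dist[FLANK - 2]))
                if dist[FLANK - 1] == prox[FLANK - 1]:
                    put_dist(FLANK - 1, _pick_other(rng, prox[FLANK - 1]))
            else:
                # substituted block ends 2 bases 5' of the MH stretch
                end_i = FLANK - mh - 2
                start_i = end_i - len(ref_alleles) + 1
                for k, base in enumerate(ref_alleles):
                    put_prox(start_i + k, base)
                if mh > 0:
                    for k in range(mh):
                        put_dist(FLANK - mh + k, prox[FLANK - mh + k])
                if dist[FLANK - mh - 1] == prox[FLANK - mh - 1]:
                    put_dist(FLANK - mh - 1,
                             _pick_other(rng, prox[FLANK - mh - 1]))

        insert = spec.insert_seq
        if insert:
            if insert[0] == dist[FLANK]:
                put_dist(FLANK, _pick_other(rng, insert[0], prox[FLANK]))
            if insert[-1] == prox[FLANK - 1]:
                put_prox(FLANK - 1, _pick_other(rng, insert[-1],
                                                dist[FLANK - 1]))

        prox_s = "".join(prox)
        dist_s = "".join(dist)
        clean_junction = prox_s[:FLANK] + dist_s[FLANK:]

        junction = clean_junction
        if insert:
            junction = prox_s[:FLANK] + insert + dist_s[FLANK:]
        if scar_kind == "deletion":
            junction = prox_s[:FLANK - 1] + dist_s[FLANK:]
        elif scar_kind == "substitution":
            end_i = FLANK - mh - 2
            start_i = end_i - len(ref_alleles) + 1
            j = list(junction)
            for k, base in enumerate(alt_alleles):
                j[start_i + k] = base
            junction = "".join(j)

        case_id = f"sim_{s}_{e}"
        clean_case = JunctionCase(
            case_id=case_id,
            proximal_ref=SequenceRegion(f"{case_id}_prox", prox_s, FLANK),
            distal_ref=SequenceRegion(f"{case_id}_dist", dist_s, FLANK),
            junction=clean_junction,
        )
        if max_parse_microhomology(clean_case) != mh:
            last_err = ValueError("accidental homology; resampling")
            continue  # accidental homology beyond the planted stretch

        case = JunctionCase(
            case_id=case_id,
            proximal_ref=clean_case.proximal_ref,
            distal_ref=clean_case.distal_ref,
            junction=junction,
        )
        fam_p = c1.family if c1 is not None else None
        fam_d = c2.family if c2 is not None else None
        identity = None
        if cassette_prox is not None and cassette_dist is not None \
                and len(cassette_prox) == len(cassette_dist):
            matches = sum(a == b for a, b in zip(cassette_prox, cassette_dist))
            identity = int(100 * matches / len(cassette_prox) + 0.5)
        expected = classify_mechanism(
            mh, spec.scar is not None, fam_p, fam_d, identity,
        )
        truth = SimTruth(
            spec=spec, start=s, end=e,
            family_prox=fam_p, family_dist=fam_d,
            identity_pct=identity, expected_call=expected,
        )
        return case, truth
    raise ValueError(
        f"could not plant deletion after {max_resamples} resamples: {last_err}"
    )


# ---------------------------------------------------------------------------
# Cohort mirroring the bundled deletion table

@dataclass(frozen=True)
class SyntheticCohort:
    locus: SequenceRegion
    annotations: tuple[RepeatFeature, ...]
    cases: tuple[JunctionCase, ...]
    truths: tuple[SimTruth, ...]


def make_table1_like_cohort(seed: int = 0,
                            locus_length: int = 300_000,
                            ) -> SyntheticCohort:
    """One synthetic junction case per record of the bundled cohort table.

    Each case realises the corresponding record's microhomology length, scar,
    and repeat-superfamily context on a synthetic locus (deletion sizes are
    not reproduced: they play no role in junction signatures and the largest
    exceed any practical test locus).  Running the caller plus classifier on
    the cohort reproduces the table's microhomology and mechanism columns.
    """
    from .io_model import load_table1_fixture

    locus, annotations = generate_locus(
        length=locus_length, gc=0.41, repeat_density=0.2, seed=seed,
    )
    records = load_table1_fixture()
    cases: list[JunctionCase] = []
    truths: list[SimTruth] = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 24]))
    for i, rec in enumerate(records):
        fam_p = repeat_family(rec.repeat_prox) if rec.repeat_prox else None
        fam_d = repeat_family(rec.repeat_dist) if rec.repeat_dist else None
        if fam_p is not None and fam_p == fam_d:
            ctx = "same_family_alu" if fam_p == "Alu" else "same_family_l1"
        elif fam_p is not None and fam_d is not None:
            ctx = "different_family"
        elif fam_p is not None or fam_d is not None:
            ctx = "one_side"
        else:
            ctx = "none"
        spec = DeletionSpec(
            size_bp=min(rec.end_hg19 - rec.start_hg19, 20_000),
            mh_len=rec.mh_len,
            scar=rec.scar,
            repeat_context=ctx,
            seed=int(rng.integers(0, 2**31 - 1)),
            families=(fam_p, fam_d),
        )
        case, truth = plant_deletion(locus, spec, annotations)
        case = JunctionCase(
            case_id=rec.patient_code,
            proximal_ref=case.proximal_ref,
            distal_ref=case.distal_ref,
            junction=case.junction,
        )
        cases.append(case)
        truths.append(truth)
    return SyntheticCohort(locus, tuple(annotations), tuple(cases),
                           tuple(truths))
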