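"""Architecture-scanner tests: planted features and brute-force equivalence."""

import numpy as np
import pytest

from junctionsig import (
    MotifDef,
    RepeatFeature,
    SequenceRegion,
    build_profile,
    filter_flanking,
    find_direct_repeats,
    find_inverted_repeats,
    find_mirror_repeats,
    find_tetraplex,
    find_zdna,
    pairwise_identity,
    repeat_at_breakpoint,
    revcomp,
    scan_motifs,
)
from junctionsig.architecture import g4_score

from oracles import (
    oracle_direct,
    oracle_motif_hits,
    oracle_tetraplex,
    oracle_two_armed,
    oracle_zdna,
)


def _region(seq, off=None):
    return SequenceRegion("r", seq, len(seq) // 2 if off is None else off)


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


# ---------------------------------------------------------------------------
# Motifs

def test_motif_literal_match():
    hits = scan_motifs(_region("GCTGGTGGAA"),
                       [MotifDef("chi", "chi", "GCTGGTGG", False)])
    assert [(h.start, h.end) for h in hits] == [(0, 8)]


def test_motif_degenerate_match():
    hits = scan_motifs(_region("AGTC", 2), [MotifDef("rry", "", "RRY", False)])
    assert hits[0].start == 0  # A=R, G=R, T=Y


def test_motif_overlapping_hits():
    hits = scan_motifs(_region("AAAAA", 2), [MotifDef("aa", "", "AA", False)])
    assert [h.start for h in hits] == [0, 1, 2, 3]


def test_motif_counts_match_positional_oracle(rng):
    cat = [
        MotifDef("m1", "", "GCTGGTGG", False),
        MotifDef("m2", "", "TGRRKM", False),
        MotifDef("m3", "", "RYRYRYRY", False),
        MotifDef("m4", "", "GGGNGGG", False),
        MotifDef("m5", "", "CACAGTG", False),
    ]
    for _ in range(200):
        seq = _rand(rng, 150)
        region = _region(seq)
        hits = scan_motifs(region, cat)
        for m in cat:
            got = sorted(h.start for h in hits if h.motif_id == m.motif_id)
            assert got == oracle_motif_hits(seq, m.pattern)


def test_motif_strand_consistency(rng):
    """Forward hits on a region reappear mirrored on its reverse complement."""
    cat = [MotifDef("m", "", "TGRRKM", True)]
    seq = _rand(rng, 120)
    region = _region(seq, 60)
    flipped = _region(revcomp(seq), 60)
    fwd = {(h.start, h.end, h.strand) for h in scan_motifs(region, cat)}
    rev = {(len(seq) - h.end, len(seq) - h.start,
            "+" if h.strand == "-" else "-")
           for h in scan_motifs(flipped, cat)}
    assert fwd == rev


def test_motif_empty_catalogue_rejected():
    with pytest.raises(ValueError):
        scan_motifs(_region("ACGTACGTACGT"), [])


# ---------------------------------------------------------------------------
# Direct / inverted / mirror repeats

def _contains(feat, a1, a2):
    return (feat.arm1[0] <= a1[0] and feat.arm1[1] >= a1[1]
            and feat.arm2[0] <= a2[0] and feat.arm2[1] >= a2[1])


def test_direct_repeat_planted(rng):
    arm = "ACGTTGCAGT"
    bg = _rand(rng, 150)
    seq = (bg[:40] + arm + bg[50:70] + arm + bg[80:150])[:150]
    feats = find_direct_repeats(_region(seq, 75))
    # maximal extension may absorb chance matches at the arm boundaries, so
    # assert one reported pair covering the planted arms
    planted = [f for f in feats if _contains(f, (40, 50), (70, 80))]
    assert len(planted) == 1
    assert planted[0].score >= 10


def test_homopolymer_suppressed():
    feats = find_direct_repeats(_region("A" * 150, 75))
    assert feats == []


def test_dinucleotide_arm_suppressed():
    # plain AC repeat arms carry exactly 1 bit of entropy: filtered
    feats = find_direct_repeats(_region("ACACACACACACACACACAC" + "T" * 40, 30))
    assert feats == []


def test_direct_repeat_flanks_breakpoint(rng):
    arm = "ACGTTGCAGT"
    bg = _rand(rng, 150)
    seq = (bg[:60] + arm + bg[70:90] + arm + bg[100:150])[:150]
    feats = find_direct_repeats(_region(seq, 75))
    planted = next(f for f in feats if _contains(f, (60, 70), (90, 100)))
    assert planted.flanks_breakpoint  # arms at 60-70 and 90-100 straddle 75


def test_inverted_repeat_planted(rng):
    arm = "GGGCCCATTA"
    bg = _rand(rng, 150)
    seq = (bg[:40] + arm + bg[50:70] + revcomp(arm) + bg[80:150])[:150]
    feats = find_inverted_repeats(_region(seq, 75))
    assert any(_contains(f, (40, 50), (70, 80)) for f in feats)


def test_mirror_repeat_planted(rng):
    arm = "ACCTGATTGC"
    bg = _rand(rng, 150)
    seq = (bg[:40] + arm + bg[50:70] + arm[::-1] + bg[80:150])[:150]
    feats = find_mirror_repeats(_region(seq, 75))
    assert any(_contains(f, (40, 50), (70, 80)) for f in feats)


def test_short_arm_not_reported(rng):
    arm = "GGGCCCA"  # 7 < min_arm 8
    bg = _rand(rng, 150)
    seq = (bg[:40] + arm + bg[47:70] + revcomp(arm) + bg[77:150])[:150]
    feats = find_inverted_repeats(_region(seq, 75))
    assert not any(f.arm1 == (40, 47) for f in feats)


# ---------------------------------------------------------------------------
# Tetraplex and Z-DNA

def test_tetraplex_telomeric():
    seq = "ACTACT" + "GGGTTAGGGTTAGGGTTAGGG" + "ACTACTACTACTAC"
    feats = find_tetraplex(_region(seq, 10))
    assert len(feats) == 1
    f = feats[0]
    assert f.arm1 == (6, 27)
    assert f.score == g4_score(3, (3, 3, 3))


def test_tetraplex_run_length_monotonicity():
    strong = find_tetraplex(_region("ACTACT" + "GGGTTAGGGTTAGGGTTAGGG"
                                    + "ACTACTACTACTAC", 10))[0]
    weak = find_tetraplex(_region("ACTACT" + "GGTTGGTTGGTTGG"
                                  + "ACTACTACTACTACAACCA", 10))[0]
    assert weak.score < strong.score


def test_zdna_gt_tract():
    feats = find_zdna(_region("AATTAA" + "GTGTGTGTGTGTGT" + "AATTAATTAATT", 10))
    assert len(feats) == 1
    assert feats[0].score == 14
    assert feats[0].arm1 == (6, 20)


def test_zdna_ag_steps_excluded():
    assert find_zdna(_region("GAGAGAGAGAGAGAGA" + "TTTTAAAATTTTAAAA", 16)) == []


def test_zdna_interrupted_tract_dropped():
    # two 8-base halves split by an AA interruption: both below min_len 12
    seq = "TTAA" + "GTGTGTGT" + "AA" + "GTGTGTGT" + "TTAATTAATTAA"
    assert find_zdna(_region(seq, 17)) == []


# ---------------------------------------------------------------------------
# Oracle equivalence (shared random strings, all detectors)

def test_scanners_match_brute_force(rng):
    """Every detector agrees with its exhaustive oracle on random strings."""
    cat = [MotifDef("m1", "", "TGRRKM", False),
           MotifDef("m2", "", "GGGNGGG", False)]
    for _ in range(120):
        n = int(rng.integers(30, 201))
        seq = _rand(rng, n)
        region = _region(seq, max(1, n // 2))

        for m in cat:
            got = sorted(h.start for h in scan_motifs(region, cat)
                         if h.motif_id == m.motif_id)
            assert got == oracle_motif_hits(seq, m.pattern)

        got = {(f.arm1[0], f.arm1[1], f.arm2[0], f.arm2[1])
               for f in find_direct_repeats(region)}
        assert got == oracle_direct(seq, 8, 120)

        got = {(f.arm1[0], f.arm1[1], f.arm2[0], f.arm2[1])
               for f in find_inverted_repeats(region)}
        assert got == oracle_two_armed(seq, "inverted", 8, 120)

        got = {(f.arm1[0], f.arm1[1], f.arm2[0], f.arm2[1])
               for f in find_mirror_repeats(region)}
        assert got == oracle_two_armed(seq, "mirror", 8, 120)

        assert [(f.arm1[0], f.arm1[1]) for f in find_zdna(region)] == \
            oracle_zdna(seq)


def test_tetraplex_scores_match_enumeration_oracle(rng):
    """On G-rich strings the selected candidates carry exactly the scores of
    the greedy reduction of the exhaustively enumerated decompositions."""
    for _ in range(100):
        n = int(rng.integers(40, 120))
        seq = "".join(rng.choice(list("ACGT"), n, p=[0.15, 0.15, 0.55, 0.15]))
        region = _region(seq, max(1, n // 2))
        cands = sorted(oracle_tetraplex(seq), key=lambda c: (-c[0], c[1], c[2]))
        chosen = []
        for score, s, e in cands:
            if all(e <= cs or s >= ce for _, cs, ce in chosen):
                chosen.append((score, s, e))
        chosen.sort(key=lambda c: c[1])
        got = [(f.score, f.arm1[0], f.arm1[1]) for f in find_tetraplex(region)]
        assert got == chosen


# ---------------------------------------------------------------------------
# Filtering, repeat intersection, identity

def test_filter_flanking_definition(rng):
    arm = "ACGTTGCAGT"
    bg = _rand(rng, 150)
    # both arms 5' of the breakpoint: removed by the flanking filter
    seq = (bg[:10] + arm + bg[20:40] + arm + bg[50:150])[:150]
    region = _region(seq, 75)
    feats = [f for f in find_direct_repeats(region)
             if _contains(f, (10, 20), (40, 50))]
    assert feats and not feats[0].flanks_breakpoint
    assert feats[0] not in filter_flanking(feats, region)


def test_filter_flanking_overlap_kept():
    seq = "ATCATCATC" + "GGGTTAGGGTTAGGGTTAGGG" + "ATCATCATCATCATCATC"
    region = _region(seq, 15)  # breakpoint inside the G4 tract
    feats = find_tetraplex(region)
    assert feats[0].flanks_breakpoint
    assert filter_flanking(feats, region) == feats


def test_filter_never_increases(rng):
    seq = _rand(rng, 150)
    region = _region(seq, 75)
    feats = find_direct_repeats(region) + find_zdna(region)
    assert len(filter_flanking(feats, region)) <= len(feats)


def test_repeat_at_breakpoint():
    alu = RepeatFeature("chr3", 1000, 1310, "AluY", "Alu", "+")
    assert repeat_at_breakpoint(1200, [alu]) == alu
    assert repeat_at_breakpoint(1311, [alu]) is None
    assert repeat_at_breakpoint(999, [alu]) is None
    # tie: the repeat with the larger overlap of the 150-bp window wins
    small = RepeatFeature("chr3", 1190, 1210, "MIRb", "MIR", "+")
    assert repeat_at_breakpoint(1200, [small, alu]) == alu


def test_pairwise_identity_exact_cases(rng):
    a = _rand(rng, 300)
    assert pairwise_identity(a, a) == 100
    b = list(a)
    idx = rng.choice(300, 30, replace=False)
    for i in idx:
        b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
    assert pairwise_identity(a, "".join(b)) == 90


def test_pairwise_identity_l1_like_divergence(rng):
    """Two decoy copies mutated 2% each sit near 96% identity, the regime of
    the most similar repeat pair in the cohort."""
    cons = _rand(rng, 1500)
    def mutate(s, rate):
        out = list(s)
        for i in np.where(rng.random(len(s)) < rate)[0]:
            out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
        return "".join(out)
    a, b = mutate(cons, 0.02), mutate(cons, 0.02)
    hamming = round(100 * sum(x == y for x, y in zip(a, b)) / len(a))
    ident = pairwise_identity(a, b)
    assert abs(ident - hamming) <= 1
    assert 94 <= ident <= 98


def test_pairwise_identity_input_validation():
    with pytest.raises(ValueError):
        pairwise_identity("", "ACGT" * 30)
    with pytest.raises(ValueError):
        pairwise_identity("ACGT", "ACGT" * 30)


def test_profile_counts_consistent(rng):
    from junctionsig import load_motif_catalogue
    seq = _rand(rng, 150)
    profile = build_profile(_region(seq, 75), load_motif_catalogue())
    assert profile.motif_count == len(profile.motif_hits)
    assert profile.nonb_count == len(profile.nonb_features)
    assert all(f.flanks_breakpoint for f in profile.nonb_features)
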