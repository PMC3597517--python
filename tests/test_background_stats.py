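"""Control-population and enrichment-statistics tests."""

import numpy as np
import pytest
from scipy import stats

from junctionsig import (
    ControlSet,
    SequenceRegion,
    bonferroni,
    control_microhomology,
    enrichment_report,
    fisher_exact_2x2,
    sample_control_regions,
    wilcoxon_rank_sum,
)
from junctionsig.background_stats import CONTROL_BREAKPOINT

from oracles import oracle_fisher_two_sided, oracle_rank_sum_exact


# ---------------------------------------------------------------------------
# Fisher's exact test

def test_fisher_printed_repeat_enrichment():
    """31/48 observed vs 236/500 control breakpoints with a repeat."""
    _, p = fisher_exact_2x2(31, 17, 236, 264)
    assert round(p, 3) == 0.024


def test_fisher_printed_nonb():
    _, p = fisher_exact_2x2(14, 34, 107, 393)
    assert round(p, 3) == 0.208


def test_fisher_equal_proportions():
    _, p = fisher_exact_2x2(5, 5, 5, 5)
    assert p == 1.0


def test_fisher_degenerate_margin():
    _, p = fisher_exact_2x2(0, 0, 3, 4)
    assert p == 1.0


def test_fisher_matches_enumeration_oracle(rng):
    for _ in range(80):
        a, b, c, d = (int(v) for v in rng.integers(0, 13, 4))
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        _, p = fisher_exact_2x2(a, b, c, d)
        assert p == pytest.approx(oracle_fisher_two_sided(a, b, c, d),
                                  rel=1e-6, abs=1e-12)


def test_fisher_small_table_enumeration():
    _, p = fisher_exact_2x2(2, 3, 4, 1)
    assert p == pytest.approx(oracle_fisher_two_sided(2, 3, 4, 1), rel=1e-9)


def test_fisher_swap_invariance(rng):
    for _ in range(30):
        a, b, c, d = (int(v) for v in rng.integers(1, 20, 4))
        _, p = fisher_exact_2x2(a, b, c, d)
        _, p_rows = fisher_exact_2x2(c, d, a, b)
        _, p_cols = fisher_exact_2x2(b, a, d, c)
        _, p_both = fisher_exact_2x2(d, c, b, a)
        assert p == pytest.approx(p_rows) == pytest.approx(p_cols) \
            == pytest.approx(p_both)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def test_rank_sum_identical_samples():
    assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_rank_sum_fully_separated():
    # 2 of the 20 assignments are at least as extreme
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_rank_sum_all_tied():
    assert wilcoxon_rank_sum([2, 2], [2, 2, 2]) == 1.0


def test_rank_sum_matches_permutation_oracle(rng):
    for _ in range(20):
        n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        x = [float(v) for v in rng.integers(0, 6, n)]
        y = [float(v) for v in rng.integers(0, 6, m)]
        if len(set(x + y)) == 1:
            continue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(
            oracle_rank_sum_exact(x, y))


def test_rank_sum_large_sample_uses_tie_corrected_normal(rng):
    x = [int(v) for v in rng.integers(0, 4, 30)]
    y = [int(v) for v in rng.integers(0, 6, 40)]
    expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue
    assert wilcoxon_rank_sum(x, y) == pytest.approx(float(expected))


def test_rank_sum_input_validation():
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([1], [2, 3])


# ---------------------------------------------------------------------------
# Bonferroni

def test_bonferroni_examples():
    assert bonferroni(0.0005, 2) == 0.001
    assert bonferroni(0.9, 5) == 1.0


def test_bonferroni_monotone():
    ps = np.linspace(0, 1, 21)
    for k in (1, 2, 5):
        vals = [bonferroni(p, k) for p in ps]
        assert vals == sorted(vals)
    for p in (0.001, 0.3):
        vals = [bonferroni(p, k) for k in range(1, 10)]
        assert vals == sorted(vals)


# ---------------------------------------------------------------------------
# Control population

def test_control_sampling_deterministic(uniform_locus):
    c1 = sample_control_regions([uniform_locus], n=100, seed=17)
    c2 = sample_control_regions([uniform_locus], n=100, seed=17)
    assert [r.seq for r in c1.regions] == [r.seq for r in c2.regions]
    assert all(r.breakpoint_offset == CONTROL_BREAKPOINT for r in c1.regions)


def test_control_sampling_rejects_all_n():
    ref = SequenceRegion("n", "N" * 800_000, 100)
    with pytest.raises(ValueError):
        sample_control_regions([ref], n=500, seed=1)


def test_control_sampling_rejects_short_reference():
    ref = SequenceRegion("s", "ACGT" * 100, 100)
    with pytest.raises(ValueError, match="too short"):
        sample_control_regions([ref], n=500, seed=1)


def test_control_positions_uniform(uniform_locus):
    """Chi-square on 10 position bins stays above p = 0.001 for 20 seeds."""
    n_bins = 10
    length = len(uniform_locus.seq)
    for seed in range(20):
        ctrl = sample_control_regions([uniform_locus], n=500, seed=seed)
        starts = [int(r.id.rsplit(":", 1)[1]) for r in ctrl.regions]
        counts, _ = np.histogram(starts, bins=n_bins, range=(0, length))
        _, p = stats.chisquare(counts)
        assert p > 0.001


def test_identical_pair_gives_saturated_mh(uniform_locus):
    region = sample_control_regions([uniform_locus], n=1, seed=2).regions[0]
    twin = SequenceRegion("twin", region.seq, region.breakpoint_offset)
    ctrl = ControlSet(regions=(region, twin), pairing=((0, 1),), seed=0,
                      source="test")
    assert control_microhomology(ctrl)[0] >= 75


# ---------------------------------------------------------------------------
# Enrichment report

def _profile(region_id, repeat=None, motif_ids=(), nonb_kinds=()):
    from junctionsig.architecture import ArchitectureProfile, MotifHit, NonBFeature
    hits = tuple(MotifHit(m, 0, 5, "+") for m in motif_ids)
    nonb = tuple(NonBFeature(k, (70, 80), None, 10.0, True)
                 for k in nonb_kinds)
    return ArchitectureProfile(region_id, repeat, hits, nonb)


def test_enrichment_identical_populations_all_null():
    profiles = [_profile(f"r{i}", motif_ids=("m1",),
                         nonb_kinds=("zdna",) if i % 2 else ())
                for i in range(10)]
    rep = enrichment_report(profiles, profiles, [0, 1] * 5, [0, 1] * 5)
    assert all(r.p_two_sided == pytest.approx(1.0) for r in rep.contingency)
    assert rep.mh_distribution_p == pytest.approx(1.0)
    assert rep.motif_density_p == pytest.approx(1.0)


def test_enrichment_subgroup_comparison():
    enc = [_profile(f"e{i}", nonb_kinds=("tetraplex",) if i < 13 else ())
           for i in range(32)]
    reg = [_profile(f"r{i}", nonb_kinds=("tetraplex",) if i < 1 else ())
           for i in range(16)]
    ctl = [_profile(f"c{i}") for i in range(10)]
    rep = enrichment_report(enc + reg, ctl, [1] * 48, [0] * 10,
                            observed_subgroups=["foxl2_encompassing"] * 32
                            + ["regulatory"] * 16)
    sub = next(r for r in rep.contingency
               if r.label == "nonb_encompassing_vs_regulatory")
    assert (sub.a, sub.b, sub.c, sub.d) == (13, 19, 1, 15)
    assert round(sub.p_two_sided, 3) == 0.018


def test_enrichment_corrected_at_least_raw():
    profiles = [_profile(f"r{i}", motif_ids=("m1", "m2")) for i in range(6)]
    ctl = [_profile(f"c{i}", motif_ids=("m1",)) for i in range(6)]
    rep = enrichment_report(profiles, ctl, [1] * 6, [0] * 6, catalogue_size=40)
    for r in rep.contingency:
        assert 0 <= r.p_two_sided <= 1
        if r.p_corrected is not None:
            assert r.p_corrected >= r.p_two_sided
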