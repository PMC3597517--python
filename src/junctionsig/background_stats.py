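"""Random-control breakpoint population and enrichment statistics.

Observed junction signatures are compared against a random control population
of artificial breakpoint regions: 150-bp sequences drawn uniformly from a
reference, each carrying an artificial breakpoint between nucleotides 75 and
76.  Control microhomology is measured on pseudo-junctions formed by joining
the left flank of one control region to the right flank of the next (cyclic
pairing keeps the population size at n), using the same caller as for
observed junctions with zero scar tolerance.

Enrichment is assessed with two-sided Fisher's exact tests on presence/absence
contingency tables (overall repeats, per repeat family with Bonferroni
correction, per motif, non-B DNA overall and per kind) and with Wilcoxon
rank-sum tests on the microhomology-length and motif-density distributions.
For uniform iid flanks the analytic microhomology distribution is geometric on
each side of the breakpoint: P(mh = 0) = (3/4)^2 = 0.5625 and
P(mh <= 1) = 0.84375, so control microhomology clusters at 0-1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_model import SequenceRegion
from .junctions import call_microhomology
from .io_model import JunctionCase
from .architecture import ArchitectureProfile

CONTROL_N = 500
CONTROL_REGION_LEN = 150
CONTROL_BREAKPOINT = 75


@dataclass(frozen=True)
class ControlSet:
    """A random population of artificial breakpoint regions."""

    regions: tuple[SequenceRegion, ...]
    pairing: tuple[tuple[int, int], ...]
    seed: int
    source: str

    def __post_init__(self) -> None:
        for r in self.regions:
            if r.breakpoint_offset != CONTROL_BREAKPOINT:
                raise ValueError("control regions must break between nt 75 and 76")


@dataclass(frozen=True)
class ContingencyResult:
    """A labelled 2x2 presence/absence comparison.

    Cells: a/b observed with/without the feature, c/d control with/without.
    """

    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p_two_sided: float
    p_corrected: Optional[float] = None
    correction: str = "none"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if not 0 <= self.p_two_sided <= 1:
            raise ValueError("p outside [0, 1]")
        if self.p_corrected is not None and self.p_corrected < self.p_two_sided:
            raise ValueError("corrected p below raw p")


def sample_control_regions(reference: Sequence[SequenceRegion],
                           n: int = CONTROL_N,
                           seed: int = 0) -> ControlSet:
    """Draw n 150-bp regions at uniform random positions from a reference.

    Windows containing N are rejected and redrawn.  The same seed yields the
    same control set.
    """
    total = sum(len(r) for r in reference)
    if total < 10 * n * CONTROL_REGION_LEN:
        raise ValueError(
            f"reference too short for {n} control regions "
            f"({total} < {10 * n * CONTROL_REGION_LEN} nt)"
        )
    rng = np.random.default_rng(seed)
    usable = [r for r in reference if len(r) >= CONTROL_REGION_LEN]
    weights = np.array([len(r) - CONTROL_REGION_LEN + 1 for r in usable], float)
    weights /= weights.sum()
    regions: list[SequenceRegion] = []
    attempts = 0
    while len(regions) < n:
        attempts += 1
        if attempts > 100 * n:
            raise ValueError("could not draw N-free control windows")
        src = usable[rng.choice(len(usable), p=weights)]
        start = int(rng.integers(0, len(src) - CONTROL_REGION_LEN + 1))
        window = src.seq[start:start + CONTROL_REGION_LEN]
        if "N" in window:
            continue
        regions.append(
            SequenceRegion(
                id=f"ctrl_{len(regions)}|{src.id}:{start}",
                seq=window,
                breakpoint_offset=CONTROL_BREAKPOINT,
            )
        )
    pairing = tuple((i, (i + 1) % n) for i in range(n))
    return ControlSet(tuple(regions), pairing, seed,
                      source=",".join(r.id for r in reference[:3]))


def control_microhomology(ctrl: ControlSet) -> list[int]:
    """Microhomology lengths of the control pseudo-junctions.

    Region i acts as the proximal reference and its partner as the distal
    reference; the pseudo-junction joins i's left flank to the partner's
    right flank at the artificial breakpoint.  Zero scar tolerance.
    """
    out: list[int] = []
    for i, j in ctrl.pairing:
        prox, dist = ctrl.regions[i], ctrl.regions[j]
        junction = (prox.seq[:prox.breakpoint_offset]
                    + dist.seq[dist.breakpoint_offset:])
        case = JunctionCase(
            case_id=f"ctrl_{i}_{j}",
            proximal_ref=prox,
            distal_ref=dist,
            junction=junction,
        )
        out.append(call_microhomology(case, max_scar_mismatches=0).mh_len)
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    The two-sided p sums the probabilities of all tables with the observed
    margins whose hypergeometric point probability does not exceed that of
    the observed table.  Degenerate margins give p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if (a + b == 0 or c + d == 0) or (a + c == 0 or b + d == 0):
        odds = np.nan
        return odds, 1.0
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value with midranks for ties.

    For combined sample sizes up to 20 the exact permutation distribution of
    the rank sum is enumerated; larger samples use the normal approximation
    with tie and continuity corrections.
    """
    x = list(x)
    y = list(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per sample")
    pooled = x + y
    if len(set(pooled)) == 1:
        return 1.0
    n, m = len(x), len(y)
    if n + m <= 20:
        ranks = stats.rankdata(pooled)
        observed = ranks[:n].sum()
        mean = n * (n + m + 1) / 2.0
        obs_dev = abs(observed - mean)
        total = 0
        extreme = 0
        for idx in combinations(range(n + m), n):
            total += 1
            s = sum(ranks[i] for i in idx)
            if abs(s - mean) >= obs_dev - 1e-9:
                extreme += 1
        return extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def bonferroni(p: float, k: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * k)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return min(1.0, p * k)


@dataclass(frozen=True)
class EnrichmentReport:
    """All observed-vs-control comparisons for one analysis run."""

    contingency: tuple[ContingencyResult, ...]
    mh_distribution_p: float
    motif_density_p: float
    motif_density_means: tuple[float, float]  # observed, control


def _presence(profiles: Sequence[ArchitectureProfile], what: str,
              kind: Optional[str] = None) -> tuple[int, int]:
    with_feat = 0
    for pr in profiles:
        if what == "repeat":
            present = pr.repeat_at_breakpoint is not None
            if present and kind is not None:
                present = pr.repeat_at_breakpoint.family == kind
        elif what == "nonb":
            feats = pr.nonb_features
            if kind is not None:
                feats = tuple(f for f in feats if f.kind == kind)
            present = len(feats) > 0
        else:
            raise ValueError(what)
        with_feat += present
    return with_feat, len(profiles) - with_feat


def enrichment_report(profiles_observed: Sequence[ArchitectureProfile],
                      profiles_control: Sequence[ArchitectureProfile],
                      mh_observed: Sequence[int],
                      mh_control: Sequence[int],
                      catalogue_size: Optional[int] = None,
                      observed_subgroups: Optional[Sequence[str]] = None,
                      ) -> EnrichmentReport:
    """Run the full battery of observed-vs-control comparisons.

    Emits: microhomology presence (Fisher) and distribution (Wilcoxon);
    repeat intersection overall and per family (Alu, L1; Bonferroni over the
    two families); per-motif presence with Bonferroni over the catalogue
    size; motif-density Wilcoxon; non-B DNA overall and per kind; and, when
    ``observed_subgroups`` labels the observed regions, a gene-encompassing
    vs regulatory comparison of non-B presence within the observed set.
    """
    if not profiles_observed or not profiles_control:
        raise ValueError("both populations must be non-empty")
    results: list[ContingencyResult] = []

    # (i) microhomology
    a = sum(1 for v in mh_observed if v >= 1)
    b = len(mh_observed) - a
    c = sum(1 for v in mh_control if v >= 1)
    d = len(mh_control) - c
    odds, p = fisher_exact_2x2(a, b, c, d)
    results.append(ContingencyResult("mh_presence", a, b, c, d, odds, p))
    mh_p = wilcoxon_rank_sum(list(mh_observed), list(mh_control))

    # (ii) repeats, overall then per family
    a, b = _presence(profiles_observed, "repeat")
    c, d = _presence(profiles_control, "repeat")
    odds, p = fisher_exact_2x2(a, b, c, d)
    results.append(ContingencyResult("repeat_any", a, b, c, d, odds, p))
    families = ("Alu", "L1")
    for fam in families:
        a, b = _presence(profiles_observed, "repeat", fam)
        c, d = _presence(profiles_control, "repeat", fam)
        odds, p = fisher_exact_2x2(a, b, c, d)
        results.append(
            ContingencyResult(f"repeat_{fam}", a, b, c, d, odds, p,
                              bonferroni(p, len(families)),
                              f"bonferroni x{len(families)}")
        )

    # (iii) per-motif presence
    motif_ids = sorted(
        {h.motif_id for pr in profiles_observed for h in pr.motif_hits}
        | {h.motif_id for pr in profiles_control for h in pr.motif_hits}
    )
    k = catalogue_size if catalogue_size is not None else max(len(motif_ids), 1)
    for mid in motif_ids:
        a = sum(1 for pr in profiles_observed
                if any(h.motif_id == mid for h in pr.motif_hits))
        b = len(profiles_observed) - a
        c = sum(1 for pr in profiles_control
                if any(h.motif_id == mid for h in pr.motif_hits))
        d = len(profiles_control) - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        results.append(
            ContingencyResult(f"motif_{mid}", a, b, c, d, odds, p,
                              bonferroni(p, k), f"bonferroni x{k}")
        )
    dens_obs = [pr.motif_count for pr in profiles_observed]
    dens_ctl = [pr.motif_count for pr in profiles_control]
    density_p = wilcoxon_rank_sum(dens_obs, dens_ctl)

    # (iv) non-B DNA, overall and per kind
    a, b = _presence(profiles_observed, "nonb")
    c, d = _presence(profiles_control, "nonb")
    odds, p = fisher_exact_2x2(a, b, c, d)
    results.append(ContingencyResult("nonb_any", a, b, c, d, odds, p))
    for kind in ("direct_repeat", "inverted_repeat", "mirror_repeat",
                 "tetraplex", "zdna"):
        a, b = _presence(profiles_observed, "nonb", kind)
        c, d = _presence(profiles_control, "nonb", kind)
        odds, p = fisher_exact_2x2(a, b, c, d)
        results.append(ContingencyResult(f"nonb_{kind}", a, b, c, d, odds, p))

    # (v) within-observed subgroup comparison of non-B presence
    if observed_subgroups is not None:
        if len(observed_subgroups) != len(profiles_observed):
            raise ValueError("one subgroup label per observed profile")
        enc = [pr for pr, g in zip(profiles_observed, observed_subgroups)
               if g == "foxl2_encompassing"]
        reg = [pr for pr, g in zip(profiles_observed, observed_subgroups)
               if g == "regulatory"]
        if enc and reg:
            a, b = _presence(enc, "nonb")
            c, d = _presence(reg, "nonb")
            odds, p = fisher_exact_2x2(a, b, c, d)
            results.append(
                ContingencyResult("nonb_encompassing_vs_regulatory",
                                  a, b, c, d, odds, p)
            )

    return EnrichmentReport(
        contingency=tuple(results),
        mh_distribution_p=mh_p,
        motif_density_p=density_p,
        motif_density_means=(float(np.mean(dens_obs)), float(np.mean(dens_ctl))),
    )
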