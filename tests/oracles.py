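"""Independent brute-force oracles used to check the fast implementations.

Everything here is written for clarity, not speed, and deliberately avoids
the code paths of the package: junction parses are enumerated literally,
motif matches are checked position by position against IUPAC base sets,
repeat-arm pairs are collected from an exhaustive enumeration of matching
position pairs, and the exact tests enumerate whole null distributions.
"""

from __future__ import annotations

import math
from itertools import combinations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_max_mh(junction: str, prox: str, dist: str,
                  min_anchor: int = 10) -> int:
    """Maximum two-sided microhomology over every split parse of a junction.

    Every split position i is tried literally: the parse is valid when the
    junction prefix equals the proximal prefix and the junction suffix equals
    the distal suffix; for each valid parse the agreement of the two
    references is counted walking left and right from the implied breakpoints.
    """
    n = len(junction)
    best = None
    for i in range(min_anchor, n - min_anchor + 1):
        tail = n - i
        if junction[:i] != prox[:i]:
            continue
        if junction[i:] != dist[len(dist) - tail:]:
            continue
        j = len(dist) - tail
        left = 0
        while left < i and left < j and prox[i - 1 - left] == dist[j - 1 - left] \
                and prox[i - 1 - left] != "N":
            left += 1
        right = 0
        while i + right < len(prox) and j + right < len(dist) \
                and prox[i + right] == dist[j + right] \
                and prox[i + right] != "N":
            right += 1
        mh = left + right
        if best is None or mh > best:
            best = mh
    if best is None:
        raise ValueError("no valid parse")
    return best


def oracle_motif_hits(seq: str, pattern: str) -> list[int]:
    """Start positions of all (overlapping) IUPAC-pattern matches."""
    hits = []
    for i in range(len(seq) - len(pattern) + 1):
        if all(seq[i + k] in IUPAC[c] for k, c in enumerate(pattern)):
            hits.append(i)
    return hits


def _entropy(s: str) -> float:
    h = 0.0
    for b in set(s):
        p = s.count(b) / len(s)
        h -= p * math.log2(p)
    return h


def _maximal_segments(pairs: set[tuple[int, int]]):
    """Group matched (u, v) pairs by their diagonal constant and return the
    maximal contiguous u-segments on each diagonal."""
    by_const: dict[int, list[int]] = {}
    for u, v in pairs:
        by_const.setdefault(u + v, []).append(u)
    for m, us in sorted(by_const.items()):
        us = sorted(us)
        seg = [us[0]]
        for u in us[1:]:
            if u == seg[-1] + 1:
                seg.append(u)
            else:
                yield m, seg
                seg = [u]
        yield m, seg


def oracle_two_armed(seq: str, kind: str, min_arm: int,
                     max_spacer: int) -> set[tuple[int, int, int, int]]:
    """All maximal arm pairs as (arm1_start, arm1_end, arm2_start, arm2_end).

    ``kind``: inverted (arm2 = reverse complement of arm1) or mirror
    (arm2 = reverse of arm1).  Matched position pairs are enumerated
    exhaustively and grouped into maximal contiguous stretches.
    """
    n = len(seq)
    pairs = set()
    for u in range(n):
        for v in range(u + 1, n):
            a, b = seq[u], seq[v]
            if "N" in (a, b):
                continue
            if kind == "inverted" and COMP[a] == b:
                pairs.add((u, v))
            elif kind == "mirror" and a == b:
                pairs.add((u, v))
    out = set()
    for m, seg in _maximal_segments(pairs):
        a0, b0 = seg[0], seg[-1] + 1
        t = b0 - a0
        if t < min_arm:
            continue
        arm2 = (m - b0 + 1, m - a0 + 1)
        spacer = arm2[0] - b0
        if spacer > max_spacer:
            continue
        if _entropy(seq[a0:b0]) <= 1.0:
            continue
        out.add((a0, b0, arm2[0], arm2[1]))
    return out


def oracle_direct(seq: str, min_arm: int,
                  max_spacer: int) -> set[tuple[int, int, int, int]]:
    """All maximal identical arm pairs, enumerated per arm separation."""
    n = len(seq)
    out = set()
    for d in range(1, n):
        runs = []
        k = 0
        while k < n - d:
            if seq[k] == seq[k + d] and seq[k] != "N":
                start = k
                while k < n - d and seq[k] == seq[k + d] and seq[k] != "N":
                    k += 1
                runs.append((start, k - start))
            else:
                k += 1
        for start, r in runs:
            t = min(r, d)
            if t < min_arm or d - t > max_spacer:
                continue
            if _entropy(seq[start:start + t]) <= 1.0:
                continue
            out.add((start, start + t, start + d, start + d + t))
    return out


def oracle_g_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def oracle_tetraplex(seq: str, min_run: int = 2,
                     max_span: int = 30) -> list[tuple[float, int, int]]:
    """All quadruplex candidates (score, start, end), before overlap pruning."""
    runs = oracle_g_runs(seq, min_run)
    cands = []
    for quad in combinations(runs, 4):
        s, e = quad[0][0], quad[3][1]
        if e - s > max_span:
            continue
        x = min(b - a for a, b in quad)
        loops = [quad[i + 1][0] - quad[i][1] for i in range(3)]
        span = 4 * x + sum(loops)
        if span > max_span:
            continue
        a, b, c = loops
        score = 20.0 * (x - 2) + (max_span - span) - (
            abs(a - b) + abs(a - c) + abs(b - c))
        cands.append((score, s, e))
    return cands


def oracle_zdna(seq: str, min_len: int = 12) -> list[tuple[int, int]]:
    """Maximal Z-forming tracts by checking every substring."""
    steps = ({"G", "T"}, {"G", "C"}, {"A", "C"})

    def is_tract(sub: str) -> bool:
        return all(set(sub[i:i + 2]) in steps for i in range(len(sub) - 1))

    n = len(seq)
    out = []
    for i in range(n):
        for j in range(i + min_len, n + 1):
            if not is_tract(seq[i:j]):
                break
            extendable_left = i > 0 and is_tract(seq[i - 1:j])
            extendable_right = j < n and is_tract(seq[i:j + 1])
            if not extendable_left and not extendable_right:
                out.append((i, j))
    return out


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration with exact rational arithmetic."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x: int):
        return (math.comb(r1, x) * math.comb(r2, c1 - x),)

    denom = math.comb(n, c1)
    obs = point(a)[0]
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = point(x)[0]
        if px <= obs:
            total += px
    return total / denom


def oracle_rank_sum_exact(x: list[float], y: list[float]) -> float:
    """Two-sided exact rank-sum p by enumerating every label assignment."""
    from scipy.stats import rankdata

    pooled = list(x) + list(y)
    ranks = rankdata(pooled)
    n = len(x)
    mean = n * (len(pooled) + 1) / 2.0
    obs = abs(sum(ranks[:n]) - mean)
    total = extreme = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if abs(sum(ranks[i] for i in idx) - mean) >= obs - 1e-9:
            extreme += 1
    return extreme / total
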