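"""Independent brute-force oracles the test suite checks the package against.

Everything here is deliberately naive (exact rational arithmetic, O(n*m)
loops, textbook formulas) and shares no code with the implementation paths
it verifies.
"""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by full hypergeometric enumeration.

    Sums the probabilities, at fixed margins, of every table whose
    hypergeometric probability is at most that of the observed table
    (ties resolved with a 1e-7 relative tolerance), using Fraction
    arithmetic throughout.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)

    def prob(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    threshold = prob(a) * (1 + Fraction(1, 10**7))
    total = sum((prob(x) for x in range(lo, hi + 1) if prob(x) <= threshold), Fraction(0))
    return float(min(total, Fraction(1)))


def bh_step_up(p):
    """Benjamini-Hochberg by the literal step-up definition.

    Sort ascending; q at sorted rank i (1-based) is min over j >= i of
    m * p_(j) / j, capped at 1; return in the original order.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank0, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank0, m)]
        q_sorted[rank0] = min(1.0, min(candidates))
    q = np.empty(m)
    q[order] = q_sorted
    return q


def enumerate_windows(chrom_length: int, window_size: int, step_size: int):
    """Window tiling by literal enumeration of starts."""
    out = []
    start = 1
    while start <= chrom_length:
        end = min(start + window_size - 1, chrom_length)
        out.append((start, end))
        if end == chrom_length:
            break
        start += step_size
    # drop intermediate windows that begin beyond the chromosome (cannot
    # happen with start <= chrom_length) and merge duplicated tails
    dedup = []
    for w in out:
        if not dedup or w != dedup[-1]:
            dedup.append(w)
    return dedup


def window_summary_naive(records_by_sample, start, end, min_depth):
    """Per-window summary by a plain loop over (pos, meth, unmeth) triples.

    records_by_sample: {sample: {pos: (meth, unmeth)}} for one chromosome.
    Returns (site_positions, mean_levels list) over sites with depth >=
    max(min_depth, 1) in every sample.
    """
    samples = list(records_by_sample)
    positions = sorted({pos for recs in records_by_sample.values() for pos in recs})
    admitted = []
    for pos in positions:
        if not start <= pos <= end:
            continue
        if all(
            sum(records_by_sample[s].get(pos, (0, 0))) >= max(min_depth, 1) for s in samples
        ):
            admitted.append(pos)
    means = []
    for s in samples:
        levels = []
        for pos in admitted:
            m, u = records_by_sample[s].get(pos, (0, 0))
            levels.append(m / (m + u))
        means.append(sum(levels) / len(levels) if levels else float("nan"))
    return admitted, means


def all_pairs_overlaps(dmrs, features):
    """O(n*m) interval overlap scan on 1-based inclusive intervals.

    dmrs: list of (chrom, start, end); features: list of (chrom, start, end,
    tag). Returns the set of (dmr index, tag, overlap bp) with overlap >= 1.
    """
    hits = set()
    for i, (dc, ds, de) in enumerate(dmrs):
        for fc, fs, fe, tag in features:
            if dc != fc:
                continue
            ov = min(de, fe) - max(ds, fs) + 1
            if ov >= 1:
                hits.add((i, tag, ov))
    return hits


def complete_linkage_heights(points: np.ndarray) -> list[float]:
    """Merge heights of naive complete-linkage agglomeration on rows of
    ``points`` (Euclidean distance), sorted ascending."""
    clusters = [[i] for i in range(points.shape[0])]

    def dist(ca, cb):
        return max(
            float(np.linalg.norm(points[i] - points[j])) for i in ca for j in cb
        )

    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = dist(clusters[i], clusters[j])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights
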