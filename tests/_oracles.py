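"""Independent brute-force oracles used by the tests.

Each oracle recomputes a quantity by the most literal method available
(per-base set intersection, linear scan, exhaustive enumeration,
union-find) so the optimized implementations are checked against logic
that shares none of their code paths.
"""

from __future__ import annotations

from math import exp, lgamma

import numpy as np


def base_set(interval, exon_aware=False):
    """Explicit set of genomic base positions covered by an interval."""
    blocks = interval.exon_blocks if exon_aware else [
        (interval.start, interval.end)
    ]
    out = set()
    for s, e in blocks:
        out.update(range(s, e))
    return out


def overlap_by_bases(a, b, strand_specific=False, exon_aware=False):
    if a.chrom != b.chrom:
        return False
    if strand_specific and "." not in (a.strand, b.strand) \
            and a.strand != b.strand:
        return False
    return bool(base_set(a, exon_aware) & base_set(b, exon_aware))


def distance_by_bases(a, b):
    """Gap size counted by enumerating the bases strictly between."""
    if a.chrom != b.chrom:
        return None
    if base_set(a) & base_set(b):
        return 0
    lo = min(a.end, b.end)
    hi = max(a.start, b.start)
    return len(set(range(lo, hi)))


def linear_scan_query(intervals, chrom, start, end):
    """All intervals intersecting [start, end) on chrom, by full scan."""
    return sorted(
        (
            iv
            for iv in intervals
            if iv.chrom == chrom and iv.start < end and iv.end > start
        ),
        key=lambda iv: (iv.start, iv.end),
    )


def union_find_clusters(reads, max_distance=0, strand_specific=True):
    """O(n^2) single-linkage clustering; returns sorted footprint tuples
    with member counts."""
    n = len(reads)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def linked(a, b):
        if a.chrom != b.chrom:
            return False
        if strand_specific and a.strand != b.strand:
            return False
        gap = max(a.start, b.start) - min(a.end, b.end)
        if gap < 0:
            return True  # shared nucleotide
        if gap == 0:
            # book-ended: joined only with a positive merge window
            return max_distance > 0
        return gap <= max_distance

    for i in range(n):
        for j in range(i + 1, n):
            if linked(reads[i], reads[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(reads[i])
    out = []
    for members in groups.values():
        out.append(
            (
                members[0].chrom,
                min(m.start for m in members),
                max(m.end for m in members),
                len(members),
            )
        )
    return sorted(out)


def fisher_enumeration(a, b, rest_a, rest_b):
    """Two-sided Fisher p by exhaustive enumeration of all tables with the
    observed margins, using log-factorials only."""
    row = a + rest_a
    col = a + b
    total = a + b + rest_a + rest_b
    if total == 0:
        return 1.0

    def log_choose(n, k):
        return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)

    denom = log_choose(total, row)
    lo = max(0, col - (total - row))
    hi = min(col, row)
    pmf = [
        exp(log_choose(col, k) + log_choose(total - col, row - k) - denom)
        for k in range(lo, hi + 1)
    ]
    observed = pmf[a - lo]
    p = sum(x for x in pmf if x <= observed * (1 + 1e-9))
    return min(1.0, p)


def bh_adjust(pvalues):
    """Direct Benjamini-Hochberg step-up computation."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


def nearest_reference(query, references):
    """Linear scan for the closest same-chromosome reference (ties: first
    by input order)."""
    best = None
    for ref in references:
        if ref.chrom != query.chrom:
            continue
        gap = max(0, max(query.start, ref.start) - min(query.end, ref.end))
        if best is None or gap < best[0]:
            best = (gap, ref)
    return best
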