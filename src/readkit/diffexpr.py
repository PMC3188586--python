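"""Two-condition differential expression on arbitrary genomic regions.

The workflow is: count reads per region in each condition, normalize the
two libraries, test each region with a two-sided Fisher exact test on the
2x2 table (region count vs rest of library), and adjust the p-values with
the Benjamini-Hochberg false-discovery-rate procedure.

Three normalizations are provided:

``mean``
    Scale both libraries to the average of the two totals.  Simple, but
    distorted when highly expressed regions are themselves differential.
``interquartile``
    Assume moderately expressed regions are not differential: rank regions
    by average count and scale condition B so the interquartile regions
    carry the same total signal in both conditions.
``window``
    Counting whole regions favours long regions (more reads, more power).
    Instead, slide a window the size of the smallest region along each
    region and use the mean per-window count, removing the length bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .model import GenomicInterval, overlap_length, strands_compatible
from .store import IntervalStore


@dataclass
class CountTable:
    """Per-region read counts for two conditions plus library totals.

    Counts may be fractional after normalization or window averaging;
    raw counts are integers with ``totals >= max(counts)``.
    """

    regions: list[GenomicInterval]
    counts_a: np.ndarray
    counts_b: np.ndarray
    total_a: float
    total_b: float

    def __post_init__(self) -> None:
        self.counts_a = np.asarray(self.counts_a, dtype=float)
        self.counts_b = np.asarray(self.counts_b, dtype=float)
        if len(self.counts_a) != len(self.regions) or len(
            self.counts_b
        ) != len(self.regions):
            raise ValueError("counts length must match regions length")


@dataclass
class DiffExprRecord:
    region: GenomicInterval
    a: int
    b: int
    rest_a: int
    rest_b: int
    p_value: float
    q_value: float = 1.0
    significant: bool = False
    count_a: float = field(default=0.0)
    count_b: float = field(default=0.0)


def count_reads_per_region(
    reads: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    strand_specific: bool = False,
) -> np.ndarray:
    """Raw per-region counts: a read increments every region it overlaps
    by at least one nucleotide (a multi-region read counts in each)."""
    region_store = IntervalStore.from_intervals(
        GenomicInterval(r.chrom, r.start, r.end, r.strand, name=str(i))
        for i, r in enumerate(regions)
    )
    counts = np.zeros(len(regions), dtype=float)
    for read in reads:
        for hit in region_store.query(read.chrom, read.start, read.end):
            if strand_specific and not strands_compatible(
                read.strand, hit.strand
            ):
                continue
            counts[int(hit.name)] += 1
    region_store.close()
    return counts


def make_count_table(
    reads_a: Sequence[GenomicInterval],
    reads_b: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    strand_specific: bool = False,
) -> CountTable:
    return CountTable(
        regions=list(regions),
        counts_a=count_reads_per_region(reads_a, regions, strand_specific),
        counts_b=count_reads_per_region(reads_b, regions, strand_specific),
        total_a=len(reads_a),
        total_b=len(reads_b),
    )


# ---------------------------------------------------------------------------
# Normalizations

def normalize_mean(table: CountTable) -> CountTable:
    """Scale both libraries to the average of the two totals."""
    if table.total_a <= 0 or table.total_b <= 0:
        raise ValueError("library totals must be positive")
    target = (table.total_a + table.total_b) / 2.0
    return CountTable(
        regions=table.regions,
        counts_a=table.counts_a * (target / table.total_a),
        counts_b=table.counts_b * (target / table.total_b),
        total_a=target,
        total_b=target,
    )


def interquartile_indices(n: int) -> np.ndarray:
    """0-based ranks belonging to the interquartile set: floor(n/4)
    inclusive to floor(3n/4) exclusive, in average-count rank order."""
    return np.arange(n // 4, (3 * n) // 4)


def normalize_interquartile(table: CountTable) -> CountTable:
    """Equalize the interquartile signal of the two conditions.

    Regions are ranked by their average count over both conditions; the
    scaling factor applied to condition B (and its total) is the ratio of
    the two conditions' sums over the interquartile ranks.  Condition A is
    left untouched.
    """
    n = len(table.regions)
    if n < 4:
        raise ValueError("interquartile normalization needs >= 4 regions")
    order = np.argsort(
        (table.counts_a + table.counts_b) / 2.0, kind="stable"
    )
    iqr = order[interquartile_indices(n)]
    sum_a = float(table.counts_a[iqr].sum())
    sum_b = float(table.counts_b[iqr].sum())
    if sum_b == 0:
        raise ValueError("degenerate library: empty interquartile signal in B")
    factor = sum_a / sum_b
    return CountTable(
        regions=table.regions,
        counts_a=table.counts_a.copy(),
        counts_b=table.counts_b * factor,
        total_a=table.total_a,
        total_b=table.total_b * factor,
    )


def smallest_region_size(regions: Sequence[GenomicInterval]) -> int:
    return min(r.size for r in regions)


def window_counts(
    reads: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
    window: Optional[int] = None,
) -> np.ndarray:
    """Mean read count over a window slid 1 nt at a time along each region.

    The window defaults to the smallest region's spliced size; a region no
    longer than the window has a single placement (its plain overlap
    count).  Cost is O(region length + reads) per region via a difference
    array over window placements.
    """
    if not regions:
        raise ValueError("need at least one region")
    w = window if window is not None else smallest_region_size(regions)
    if w <= 0:
        raise ValueError("window must be positive")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = np.zeros(len(regions), dtype=float)
    for i, region in enumerate(regions):
        length = region.end - region.start
        n_pos = max(1, length - w + 1)
        eff_w = min(w, length)
        # delta[p] accumulates reads entering window placement p
        delta = np.zeros(n_pos + 1, dtype=float)
        for read in by_chrom.get(region.chrom, ()):  # noqa: B905
            # window [region.start + p, region.start + p + eff_w) overlaps
            # read [rs, re) iff rs - eff_w < region.start + p < re
            lo = max(0, read.start - eff_w + 1 - region.start)
            hi = min(n_pos - 1, read.end - 1 - region.start)
            if lo <= hi:
                delta[lo] += 1
                delta[hi + 1] -= 1
        out[i] = np.cumsum(delta[:-1]).mean()
    return out


def window_averaged_counts(
    reads_a: Sequence[GenomicInterval],
    reads_b: Sequence[GenomicInterval],
    regions: Sequence[GenomicInterval],
) -> CountTable:
    """Two-condition count table using sliding-window averaged counts."""
    w = smallest_region_size(regions)
    return CountTable(
        regions=list(regions),
        counts_a=window_counts(reads_a, regions, w),
        counts_b=window_counts(reads_b, regions, w),
        total_a=len(reads_a),
        total_b=len(reads_b),
    )


# ---------------------------------------------------------------------------
# Fisher exact test and FDR

def _log_choose(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(a: int, b: int, rest_a: int, rest_b: int,
                 alternative: str = "two-sided") -> float:
    """Fisher exact p-value for the table [[a, rest_a], [b, rest_b]].

    Two-sided: with margins fixed, sum the hypergeometric probabilities of
    every table at most as probable as the observed one.  One-sided
    alternatives ``greater``/``less`` refer to the region count in
    condition A.
    """
    for x in (a, b, rest_a, rest_b):
        if x < 0 or x != int(x):
            raise ValueError("cells must be non-negative integers")
    total = a + b + rest_a + rest_b
    if total == 0:
        return 1.0
    col = a + b              # reads in the region, both conditions
    row = a + rest_a         # library A total
    support = np.arange(max(0, col - (total - row)), min(col, row) + 1)
    # hypergeometric pmf over the support via log-gamma (vectorized)
    log_pmf = (
        _log_choose(col, support)
        + _log_choose(total - col, row - support)
        - _log_choose(total, row)
    )
    pmf = np.exp(log_pmf)
    observed = pmf[np.searchsorted(support, a)]
    if alternative == "two-sided":
        mask = pmf <= observed * (1 + 1e-10)
        if mask.all():
            return 1.0  # every table as probable as observed: exact unity
        p = pmf[mask].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, p))


def fdr_filter(
    records: Iterable[DiffExprRecord], alpha: float = 0.05
) -> list[DiffExprRecord]:
    """Benjamini-Hochberg adjustment; flags records with q <= alpha.

    The input order is preserved on return.
    """
    records = list(records)
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not records:
        return records
    pvals = np.array([r.p_value for r in records])
    _rej, qvals, _a, _b = multipletests(pvals, method="fdr_bh")
    for r, q in zip(records, qvals):
        r.q_value = float(q)
        r.significant = bool(q <= alpha)
    return records


def _round_half_even(x: float) -> int:
    return int(np.round(x))


def diff_expression(
    table: CountTable,
    normalization: str = "mean",
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> list[DiffExprRecord]:
    """Full per-region differential-expression analysis on a count table.

    ``normalization`` is one of ``mean``, ``interquartile``, ``window`` or
    ``none`` (``window`` expects the table to already hold window-averaged
    counts, built by :func:`window_averaged_counts`).  Fractional
    normalized counts are rounded half-to-even before the exact test.
    """
    if normalization == "mean":
        table = normalize_mean(table)
    elif normalization == "interquartile":
        table = normalize_interquartile(table)
    elif normalization in ("window", "none"):
        pass
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    total_a = _round_half_even(table.total_a)
    total_b = _round_half_even(table.total_b)
    out: list[DiffExprRecord] = []
    for region, ca, cb in zip(table.regions, table.counts_a, table.counts_b):
        a = min(_round_half_even(ca), total_a)
        b = min(_round_half_even(cb), total_b)
        rec = DiffExprRecord(
            region=region,
            a=a,
            b=b,
            rest_a=total_a - a,
            rest_b=total_b - b,
            p_value=fisher_exact(a, b, total_a - a, total_b - b,
                                 alternative=alternative),
            count_a=float(ca),
            count_b=float(cb),
        )
        out.append(rec)
    return fdr_filter(out, alpha=alpha)
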