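"""Distributions and coverage profiles over mapped reads.

Histograms: read size (spliced length), copy number, exons per read /
reads per cluster, nucleotide composition, chromosome density (fixed
tiles), and distance to the nearest reference feature.  Anchor profiles
aggregate per-nucleotide coverage around a transcription start/end site or
over a length-normalized gene body (meta-gene), the usual view for
comparing RNA-seq loci with ChIP-seq / MNase-seq signal.

Every plot's numeric table is also written as CSV; the CSV is the
contractual output and the PNG is best-effort rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    STRAND_REV,
    TAG_COPIES,
    TAG_ELEMENTS,
    Cluster,
    GenomicInterval,
    distance,
)

_BASES = "ACGT"
_IUPAC = set("ACGTUNRYSWKMBDHV")


@dataclass
class Histogram:
    """Ordered labelled counts; ``total`` counts the binned inputs and
    ``n_skipped`` the inputs tallied outside the bins."""

    bin_labels: list
    counts: np.ndarray
    total: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        assert int(self.counts.sum()) == self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin": self.bin_labels, "count": self.counts})


@dataclass
class AnchorProfile:
    """Mean signal at offsets relative to an anchor (nt) or relative gene
    position (bins); ``n_contributors`` counts features per offset."""

    offsets: np.ndarray
    mean_signal: np.ndarray
    n_contributors: np.ndarray
    mode: str = "tss"
    n_skipped: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "mean_signal": self.mean_signal,
                "n_contributors": self.n_contributors,
            }
        )


def _histogram_from_values(values: Sequence[int],
                           n_skipped: int = 0) -> Histogram:
    if len(values) == 0:
        return Histogram([], np.zeros(0, dtype=int), 0, n_skipped)
    labels, counts = np.unique(np.asarray(values, dtype=int),
                               return_counts=True)
    return Histogram(list(labels), counts, int(counts.sum()), n_skipped)


def size_distribution(reads: Iterable[GenomicInterval]) -> Histogram:
    """Histogram of spliced read sizes (nt)."""
    return _histogram_from_values([r.size for r in reads])


def copies_distribution(reads: Iterable[GenomicInterval]) -> Histogram:
    """Histogram of sequencing copy numbers; reads without the copies tag
    count as a single copy."""
    return _histogram_from_values(
        [int(r.tags.get(TAG_COPIES, 1)) for r in reads]
    )


def exons_distribution(
    records: Iterable[GenomicInterval | Cluster],
) -> Histogram:
    """Exons per read, or members per cluster for cluster input."""
    values = []
    for rec in records:
        if isinstance(rec, Cluster):
            values.append(rec.n_elements)
        elif TAG_ELEMENTS in rec.tags:
            values.append(int(rec.tags[TAG_ELEMENTS]))
        else:
            values.append(rec.n_exons)
    return _histogram_from_values(values)


def nucleotide_composition(
    sequences: Iterable[str], per_position: bool = False
) -> pd.DataFrame:
    """Base frequencies over all bases, or per 5'-anchored read position.

    Position p (1-based) is normalized over the reads long enough to reach
    it.  U counts as T; other IUPAC ambiguity codes are tolerated but only
    A/C/G/T enter the frequencies; non-IUPAC characters raise.
    """
    seqs = []
    for seq in sequences:
        seq = seq.upper().replace("U", "T")
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters {sorted(bad)}")
        seqs.append(seq)
    if not per_position:
        joined = "".join(seqs)
        n = sum(joined.count(b) for b in _BASES)
        if n == 0:
            raise ValueError("no unambiguous bases")
        return pd.DataFrame(
            {b: [joined.count(b) / n] for b in _BASES}, index=["frequency"]
        )
    max_len = max((len(s) for s in seqs), default=0)
    rows = []
    for pos in range(max_len):
        col = [s[pos] for s in seqs if len(s) > pos]
        n = sum(col.count(b) for b in _BASES)
        rows.append(
            {b: (col.count(b) / n if n else 0.0) for b in _BASES}
        )
    frame = pd.DataFrame(rows)
    frame.index = np.arange(1, max_len + 1)
    frame.index.name = "position"
    return frame


def density_profile(
    records: Iterable[GenomicInterval], bin_size: int
) -> dict[str, Histogram]:
    """Record counts per fixed chromosome tile of ``bin_size`` nt.

    A record belongs to the tile containing its footprint midpoint
    ``(start + end - 1) // 2``, so no record is counted twice.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    tiles: dict[str, dict[int, int]] = {}
    for r in records:
        mid = (r.start + r.end - 1) // 2
        tile = mid // bin_size
        tiles.setdefault(r.chrom, {})[tile] = (
            tiles.get(r.chrom, {}).get(tile, 0) + 1
        )
    out: dict[str, Histogram] = {}
    for chrom, counts in sorted(tiles.items()):
        max_tile = max(counts)
        arr = np.zeros(max_tile + 1, dtype=int)
        for tile, n in counts.items():
            arr[tile] = n
        labels = [t * bin_size for t in range(max_tile + 1)]
        out[chrom] = Histogram(labels, arr, int(arr.sum()))
    return out


def distance_distribution(
    queries: Sequence[GenomicInterval],
    references: Sequence[GenomicInterval],
    strand_relative: bool = False,
    max_distance: int = 10000,
) -> Histogram:
    """Distance from each query to its nearest reference.

    With ``strand_relative`` the distance is signed: negative when the
    query lies 5' (upstream) of the reference in the reference's own
    orientation, positive 3'.  Queries farther than ``max_distance`` or on
    chromosomes without references are tallied as skipped, not binned.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for ref in references:
        by_chrom.setdefault(ref.chrom, []).append(ref)
    values: list[int] = []
    n_skipped = 0
    for q in queries:
        refs = by_chrom.get(q.chrom)
        if not refs:
            n_skipped += 1
            continue
        best: Optional[tuple[int, GenomicInterval]] = None
        for ref in refs:
            d = distance(q, ref)
            if best is None or d < best[0]:
                best = (d, ref)
        d, ref = best
        if d > max_distance:
            n_skipped += 1
            continue
        if strand_relative and d > 0:
            query_is_left = q.end <= ref.start
            upstream = (
                query_is_left if ref.strand != STRAND_REV else not query_is_left
            )
            if upstream:
                d = -d
        values.append(d)
    if not values:
        return Histogram([], np.zeros(0, dtype=int), 0, n_skipped)
    labels, counts = np.unique(values, return_counts=True)
    return Histogram(list(labels), counts, int(counts.sum()), n_skipped)


# ---------------------------------------------------------------------------
# Coverage and anchor profiles

def _coverage_arrays(
    reads: Iterable[GenomicInterval],
) -> dict[str, np.ndarray]:
    """Per-chromosome per-nt read depth (every overlapping read counts at
    each exonic nucleotide)."""
    spans: dict[str, int] = {}
    blocks: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        for s, e in r.exon_blocks:
            blocks.setdefault(r.chrom, []).append((s, e))
            spans[r.chrom] = max(spans.get(r.chrom, 0), e)
    out: dict[str, np.ndarray] = {}
    for chrom, pairs in blocks.items():
        delta = np.zeros(spans[chrom] + 1, dtype=float)
        for s, e in pairs:
            delta[s] += 1
            delta[e] -= 1
        out[chrom] = np.cumsum(delta)[:-1]
    return out


def _feature_coverage(cov: dict[str, np.ndarray], chrom: str,
                      start: int, end: int) -> np.ndarray:
    """Coverage over [start, end), zero-padded outside known territory."""
    arr = cov.get(chrom)
    out = np.zeros(end - start, dtype=float)
    if arr is None:
        return out
    lo = max(0, start)
    hi = min(len(arr), end)
    if hi > lo:
        out[lo - start:hi - start] = arr[lo:hi]
    return out


def anchor_profile(
    signal_reads: Iterable[GenomicInterval],
    features: Sequence[GenomicInterval],
    anchor: str = "tss",
    flank: int = 1000,
    n_bins: int = 100,
) -> AnchorProfile:
    """Average signal coverage around an anchor or along gene bodies.

    ``tss``/``tes`` mode: per-nt coverage in ``[anchor - flank, anchor +
    flank]``, oriented 5'->3' by feature strand and averaged over
    features.  ``metagene`` mode: each feature's footprint is cut into
    ``n_bins`` equal bins of mean coverage (reversed for minus-strand
    features) and averaged; features shorter than ``n_bins`` nt are
    skipped and tallied.
    """
    if anchor not in ("tss", "tes", "metagene"):
        raise ValueError(f"unknown anchor mode {anchor!r}")
    cov = _coverage_arrays(signal_reads)
    n_skipped = 0
    if anchor in ("tss", "tes"):
        width = 2 * flank + 1
        acc = np.zeros(width)
        n = 0
        for feat in features:
            minus = feat.strand == STRAND_REV
            if anchor == "tss":
                pos = feat.end - 1 if minus else feat.start
            else:
                pos = feat.start if minus else feat.end - 1
            window = _feature_coverage(
                cov, feat.chrom, pos - flank, pos + flank + 1
            )
            acc += window[::-1] if minus else window
            n += 1
        offsets = np.arange(-flank, flank + 1)
        contributors = np.full(width, n)
        mean = acc / n if n else np.zeros(width)
        return AnchorProfile(offsets, mean, contributors, anchor, n_skipped)
    if n_bins <= 0:
        raise ValueError("n_bins must be positive")
    acc = np.zeros(n_bins)
    n = 0
    for feat in features:
        length = feat.end - feat.start
        if length < n_bins:
            n_skipped += 1
            continue
        body = _feature_coverage(cov, feat.chrom, feat.start, feat.end)
        edges = np.linspace(0, length, n_bins + 1).astype(int)
        binned = np.array(
            [body[edges[i]:edges[i + 1]].mean() for i in range(n_bins)]
        )
        acc += binned[::-1] if feat.strand == STRAND_REV else binned
        n += 1
    mean = acc / n if n else np.zeros(n_bins)
    return AnchorProfile(
        np.arange(n_bins), mean, np.full(n_bins, n), "metagene", n_skipped
    )


# ---------------------------------------------------------------------------
# Rendering

def render_plot(obj: Histogram | AnchorProfile | pd.DataFrame,
                path: str) -> str:
    """Write the numeric table as CSV next to a best-effort PNG.

    ``path`` names the image; the CSV gets the same stem.  Returns the CSV
    path.  Empty data is an error and produces no file.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(obj, Histogram):
        frame = obj.to_frame()
        kind = "bar"
    elif isinstance(obj, AnchorProfile):
        frame = obj.to_frame()
        kind = "line"
    elif isinstance(obj, pd.DataFrame):
        frame = obj.reset_index()
        kind = "line"
    else:
        raise TypeError(f"cannot plot {type(obj).__name__}")
    if frame.empty:
        raise ValueError("empty data: nothing to plot")
    csv_path = str(path).rsplit(".", 1)[0] + ".csv"
    frame.to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = frame.iloc[:, 0]
    y = frame.iloc[:, 1]
    if kind == "bar":
        ax.bar(np.arange(len(x)), y)
        step = max(1, len(x) // 20)
        ax.set_xticks(np.arange(len(x))[::step], [str(v) for v in x][::step],
                      rotation=90, fontsize=7)
    else:
        ax.plot(x, y)
    ax.set_xlabel(str(frame.columns[0]))
    ax.set_ylabel(str(frame.columns[1]))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return csv_path
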