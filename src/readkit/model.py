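"""Core genomic coordinate model.

All coordinates are 0-based, half-open ``[start, end)`` internally; readers
and writers convert at the format boundary (GFF3 and SAM are 1-based
inclusive, BED is already 0-based half-open).

A :class:`GenomicInterval` is a stranded, possibly spliced (multi-exon)
region on a named chromosome.  Mapped reads, annotations (genes,
transposable elements, ...) and merged clusters all share this one type;
aligner metadata travels in the ``tags`` mapping (hit count, mismatches,
copy number, arbitrary attributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

STRAND_FWD = "+"
STRAND_REV = "-"
STRAND_NONE = "."

#: tag keys recognized throughout the toolkit
TAG_HITS = "nbOccurrences"       # number of genomic placements of the read
TAG_MISMATCHES = "nbMismatches"  # edit distance to the reference
TAG_COPIES = "copies"            # times the identical sequence was sequenced
TAG_ELEMENTS = "nbElements"      # members merged into a cluster


class InvalidIntervalError(ValueError):
    """Raised when interval coordinates violate the model invariants."""


@dataclass
class GenomicInterval:
    """A stranded genomic region, optionally spliced into exons.

    Parameters
    ----------
    chrom : str
        Chromosome (or scaffold) name.
    start, end : int
        Footprint bounds, 0-based half-open; ``start < end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded).
    exons : list of (int, int)
        Sorted, non-overlapping sub-intervals within the footprint.  An
        empty list means a single exon spanning the footprint.
    name : str
        Record identifier.
    tags : dict
        Free-form key/value metadata (see module-level ``TAG_*`` keys).
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE
    exons: list[tuple[int, int]] = field(default_factory=list)
    name: str = ""
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise InvalidIntervalError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in (STRAND_FWD, STRAND_REV, STRAND_NONE):
            raise InvalidIntervalError(f"invalid strand {self.strand!r}")
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise InvalidIntervalError(
                    f"exon [{s}, {e}) escapes footprint "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise InvalidIntervalError("exons must be sorted and disjoint")
            prev_end = e

    # -- derived geometry -------------------------------------------------

    @property
    def exon_blocks(self) -> list[tuple[int, int]]:
        """Exons, defaulting to the whole footprint when none are set."""
        return self.exons if self.exons else [(self.start, self.end)]

    @property
    def size(self) -> int:
        """Spliced length: the sum of exon lengths, not ``end - start``.

        This is the sequenced read length for a mapped read, which is what
        size filters (e.g. the 28-30 nt piRNA window) operate on.
        """
        return sum(e - s for s, e in self.exon_blocks)

    @property
    def n_exons(self) -> int:
        return len(self.exon_blocks)

    def copy(self) -> "GenomicInterval":
        return replace(self, exons=list(self.exons), tags=dict(self.tags))

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


@dataclass
class Cluster:
    """A merged locus built from overlapping / near-adjacent records.

    ``interval`` is the merged footprint (exons merged by union);
    ``has_unique_mapper`` is true iff at least one member mapped to a
    single genomic location (hit count 1).
    """

    interval: GenomicInterval
    n_elements: int
    member_names: list[str] = field(default_factory=list)
    has_unique_mapper: bool = False

    def __post_init__(self) -> None:
        if self.n_elements < 1:
            raise InvalidIntervalError("a cluster needs at least one member")
        self.interval.tags.setdefault(TAG_ELEMENTS, self.n_elements)


def strands_compatible(a: str, b: str) -> bool:
    """Unstranded records match both strands in strand-specific tests."""
    return a == STRAND_NONE or b == STRAND_NONE or a == b


def overlaps(
    a: GenomicInterval,
    b: GenomicInterval,
    strand_specific: bool = False,
    exon_aware: bool = False,
) -> bool:
    """True iff *a* and *b* share at least one nucleotide.

    With ``exon_aware`` the test requires an exon of *a* to intersect an
    exon of *b*; otherwise the footprints are compared.  Records on
    different chromosomes never overlap.
    """
    if a.chrom != b.chrom:
        return False
    if strand_specific and not strands_compatible(a.strand, b.strand):
        return False
    if a.start >= b.end or b.start >= a.end:
        return False
    if not exon_aware:
        return True
    for s1, e1 in a.exon_blocks:
        for s2, e2 in b.exon_blocks:
            if s1 < e2 and s2 < e1:
                return True
    return False


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared footprint nucleotides (0 when disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def extend(
    a: GenomicInterval, upstream: int = 0, downstream: int = 0
) -> GenomicInterval:
    """Widen the footprint by strand-relative flanks.

    ``upstream`` extends the 5' side and ``downstream`` the 3' side: for a
    minus-strand record upstream therefore grows ``end``.  Unstranded
    records are treated as plus strand.  ``start`` is clipped at 0 and the
    exon structure is replaced by the single widened footprint.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("flanks must be non-negative")
    if a.strand == STRAND_REV:
        new_start = max(0, a.start - downstream)
        new_end = a.end + upstream
    else:
        new_start = max(0, a.start - upstream)
        new_end = a.end + downstream
    out = a.copy()
    out.start, out.end, out.exons = new_start, new_end, []
    return out


def distance(a: GenomicInterval, b: GenomicInterval) -> Optional[int]:
    """Gap between two footprints in nucleotides.

    ``None`` when chromosomes differ, 0 when the footprints overlap,
    otherwise ``max(starts) - min(ends)`` (half-open gap length; note that
    book-ended intervals are at distance 0 without overlapping).
    """
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def merge_blocks(
    blocks: Iterable[tuple[int, int]], max_gap: int = 0
) -> list[tuple[int, int]]:
    """Union of intervals, joining neighbours whose gap is <= ``max_gap``."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(blocks):
        if out and s - out[-1][1] <= max_gap:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out
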