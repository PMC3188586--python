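"""Read filtering, overlap selection against a reference set, and clustering.

These are the data-manipulation primitives of the toolkit: size and tag
filters, keep/exclude selection by overlap with (optionally flanked)
references, single-linkage clustering of mapped reads into loci, and the
detection of double-strand / divergent transcription patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import (
    STRAND_FWD,
    STRAND_NONE,
    STRAND_REV,
    TAG_ELEMENTS,
    TAG_HITS,
    TAG_MISMATCHES,
    Cluster,
    GenomicInterval,
    extend,
    merge_blocks,
    overlap_length,
    strands_compatible,
)
from .store import IntervalStore


@dataclass
class FilterSpec:
    """Constraints on read tags and spliced size (all optional, inclusive).

    ``exact_hits=1`` selects unique mappers; reads lacking a tag that a
    constraint needs are dropped (and tallied by :func:`filter_by_tags`).
    """

    min_size: Optional[int] = None
    max_size: Optional[int] = None
    max_mismatches: Optional[int] = None
    exact_hits: Optional[int] = None
    min_hits: Optional[int] = None
    max_hits: Optional[int] = None

    def __post_init__(self) -> None:
        if (
            self.min_size is not None
            and self.max_size is not None
            and self.min_size > self.max_size
        ):
            raise ValueError("min_size > max_size")


@dataclass
class TagFilterResult:
    records: list[GenomicInterval]
    n_dropped_missing_tag: int = 0


def filter_by_size(
    reads: Iterable[GenomicInterval],
    min_size: int = 0,
    max_size: Optional[int] = None,
) -> list[GenomicInterval]:
    """Keep reads whose spliced size lies in [min_size, max_size]."""
    if max_size is not None and min_size > max_size:
        raise ValueError("min_size > max_size")
    return [
        r for r in reads
        if r.size >= min_size and (max_size is None or r.size <= max_size)
    ]


def filter_by_tags(
    reads: Iterable[GenomicInterval], spec: FilterSpec
) -> TagFilterResult:
    """Keep reads satisfying every constraint present in ``spec``.

    A read missing a tag some constraint requires is dropped and counted
    in the returned tally (it cannot be proven to satisfy the constraint).
    """
    kept: list[GenomicInterval] = []
    dropped_missing = 0
    needs_hits = any(
        v is not None for v in (spec.exact_hits, spec.min_hits, spec.max_hits)
    )
    for r in reads:
        size = r.size
        if spec.min_size is not None and size < spec.min_size:
            continue
        if spec.max_size is not None and size > spec.max_size:
            continue
        if spec.max_mismatches is not None:
            mm = r.tags.get(TAG_MISMATCHES)
            if mm is None:
                dropped_missing += 1
                continue
            if mm > spec.max_mismatches:
                continue
        if needs_hits:
            hits = r.tags.get(TAG_HITS)
            if hits is None:
                dropped_missing += 1
                continue
            if spec.exact_hits is not None and hits != spec.exact_hits:
                continue
            if spec.min_hits is not None and hits < spec.min_hits:
                continue
            if spec.max_hits is not None and hits > spec.max_hits:
                continue
        kept.append(r)
    return TagFilterResult(kept, dropped_missing)


def select_by_overlap(
    queries: Sequence[GenomicInterval],
    references: Iterable[GenomicInterval] | IntervalStore,
    mode: str = "keep",
    strand_specific: bool = False,
    upstream_flank: int = 0,
    downstream_flank: int = 0,
    min_overlap: int = 1,
) -> list[GenomicInterval]:
    """Keep (or exclude) queries overlapping a reference set.

    Each reference footprint is first widened by the strand-relative
    flanks (e.g. an upstream flank selects promoter-proximal reads); a
    query matches when it shares at least ``min_overlap`` nt with some
    extended reference.  In keep mode every kept query gains an
    ``overlaps_with`` tag listing the names of its references.
    """
    if mode not in ("keep", "exclude"):
        raise ValueError(f"mode must be keep/exclude, got {mode!r}")
    extended = [
        extend(ref, upstream_flank, downstream_flank) for ref in references
    ]
    ref_store = IntervalStore.from_intervals(extended)
    out: list[GenomicInterval] = []
    for q in queries:
        hits = [
            ref
            for ref in ref_store.query(q.chrom, q.start, q.end)
            if overlap_length(q, ref) >= min_overlap
            and (
                not strand_specific
                or strands_compatible(q.strand, ref.strand)
            )
        ]
        matched = bool(hits)
        if mode == "keep" and matched:
            q = q.copy()
            q.tags["overlaps_with"] = ",".join(
                sorted({ref.name for ref in hits if ref.name})
            )
            out.append(q)
        elif mode == "exclude" and not matched:
            out.append(q)
    ref_store.close()
    return out


def _close_cluster(
    members: list[GenomicInterval], max_distance: int, strand: str,
    index: int,
) -> Cluster:
    start = min(m.start for m in members)
    end = max(m.end for m in members)
    exons = merge_blocks(
        (b for m in members for b in m.exon_blocks), max_gap=max_distance
    )
    footprint = GenomicInterval(
        members[0].chrom, start, end, strand,
        exons=exons if len(exons) > 1 else [],
        name=f"cluster_{index}",
        tags={TAG_ELEMENTS: len(members)},
    )
    return Cluster(
        interval=footprint,
        n_elements=len(members),
        member_names=[m.name for m in members],
        has_unique_mapper=any(m.tags.get(TAG_HITS) == 1 for m in members),
    )


def clusterize(
    reads: Iterable[GenomicInterval],
    max_distance: int = 0,
    strand_specific: bool = True,
) -> list[Cluster]:
    """Single-linkage merge of reads into clusters, per chromosome (and
    per strand when ``strand_specific``).

    A read joins the open cluster when it overlaps the cluster footprint,
    or trails it by a positive gap of at most ``max_distance`` nt
    (``max_distance=0`` therefore requires a shared nucleotide, not mere
    book-ended adjacency).  Output clusters are sorted by (chrom, start)
    and named ``cluster_1`` onwards.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    for r in reads:
        key = (r.chrom, r.strand if strand_specific else STRAND_NONE)
        groups.setdefault(key, []).append(r)
    raw: list[tuple[str, int, list[GenomicInterval], str]] = []
    for (chrom, strand), members in groups.items():
        members.sort(key=lambda m: (m.start, m.end))
        open_members: list[GenomicInterval] = []
        open_end = -1
        for m in members:
            joins = open_members and (
                m.start < open_end
                or (max_distance > 0 and m.start - open_end <= max_distance)
            )
            if joins:
                open_members.append(m)
                open_end = max(open_end, m.end)
            else:
                if open_members:
                    raw.append((chrom, open_members[0].start, open_members,
                                strand))
                open_members = [m]
                open_end = m.end
        if open_members:
            raw.append((chrom, open_members[0].start, open_members, strand))
    raw.sort(key=lambda t: (t[0], t[1]))
    return [
        _close_cluster(members, max_distance, strand, i + 1)
        for i, (_c, _s, members, strand) in enumerate(raw)
    ]


def filter_clusters(
    clusters: Iterable[Cluster],
    min_elements: int = 1,
    require_unique_mapper: bool = False,
) -> list[Cluster]:
    """Keep clusters with enough members and, optionally, at least one
    unique-mapping member (the cluster-rescue rule)."""
    return [
        c for c in clusters
        if c.n_elements >= min_elements
        and (not require_unique_mapper or c.has_unique_mapper)
    ]


def merge_bidirectional(
    records: Iterable[GenomicInterval], max_distance: int = 0
) -> list[Cluster]:
    """Find opposite-strand transcription patterns.

    Input records (reads or cluster footprints) are first merged into
    strand-specific clusters; an emitted locus pairs a plus and a minus
    cluster that either overlap (tag ``pattern=overlap``: double-strand
    transcription) or sit head-to-head within ``max_distance`` nt — the
    minus cluster upstream of the plus cluster (tag ``pattern=divergent``:
    a putative bidirectional promoter).
    """
    clusters = clusterize(records, max_distance=max_distance,
                          strand_specific=True)
    plus = [c for c in clusters if c.interval.strand == STRAND_FWD]
    minus = [c for c in clusters if c.interval.strand == STRAND_REV]
    out: list[Cluster] = []
    for p in plus:
        for m in minus:
            if p.interval.chrom != m.interval.chrom:
                continue
            if (
                p.interval.start < m.interval.end
                and m.interval.start < p.interval.end
            ):
                pattern = "overlap"
            elif 0 <= p.interval.start - m.interval.end <= max_distance:
                pattern = "divergent"
            else:
                continue
            start = min(p.interval.start, m.interval.start)
            end = max(p.interval.end, m.interval.end)
            footprint = GenomicInterval(
                p.interval.chrom, start, end, STRAND_NONE,
                name=f"{pattern}_{len(out) + 1}",
                tags={"pattern": pattern,
                      TAG_ELEMENTS: p.n_elements + m.n_elements},
            )
            out.append(
                Cluster(
                    interval=footprint,
                    n_elements=p.n_elements + m.n_elements,
                    member_names=p.member_names + m.member_names,
                    has_unique_mapper=p.has_unique_mapper
                    or m.has_unique_mapper,
                )
            )
    out.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return out
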