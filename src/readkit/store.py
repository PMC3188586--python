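"""Indexed interval container backed by SQLite with nested genome bins.

Overlap retrieval uses the standard 5-level genome-browser binning scheme:
bin widths 128 kb, 1 Mb, 8 Mb, 64 Mb and 512 Mb, with level offsets
585, 73, 9, 1 and 0.  Each stored interval lives in the smallest bin that
fully contains it; a range query probes only the bins that could hold an
overlapper (the ancestors of the range plus the descendants it spans) and
verifies coordinates, so query cost stays sublinear in table size even for
multi-Gb inputs that do not fit in memory.

Coordinates beyond the 512 Mb top level fall into the root bin: still
correct (the root is probed by every query), merely slower for such
outsized scaffolds.
"""

from __future__ import annotations

import json
import sqlite3
from typing import Iterable, Iterator

from .model import GenomicInterval, InvalidIntervalError

_BIN_OFFSETS = (585, 73, 9, 1, 0)
_FIRST_SHIFT = 17  # 128 kb
_NEXT_SHIFT = 3    # each level is 8x coarser
_MAX_COORD = 1 << 29  # 512 Mb: extent of the binning scheme


def bin_of(start: int, end: int) -> int:
    """Smallest nested bin fully containing ``[start, end)``.

    Intervals reaching past 512 Mb go to the root bin 0.
    """
    if start < 0 or start >= end:
        raise InvalidIntervalError(f"invalid range [{start}, {end})")
    if end > _MAX_COORD:
        return 0
    lo = start >> _FIRST_SHIFT
    hi = (end - 1) >> _FIRST_SHIFT
    for offset in _BIN_OFFSETS:
        if lo == hi:
            return offset + lo
        lo >>= _NEXT_SHIFT
        hi >>= _NEXT_SHIFT
    return 0  # pragma: no cover - level walk always terminates at offset 0


def bins_for_range(start: int, end: int) -> list[int]:
    """All bins that may hold an interval overlapping ``[start, end)``.

    This is the union, over the five levels, of the bins the range spans;
    it contains the range's own bin, its ancestors and every descendant
    bin inside the range.
    """
    if start < 0 or start >= end:
        raise InvalidIntervalError(f"invalid range [{start}, {end})")
    end = min(end, _MAX_COORD)
    start = min(start, _MAX_COORD - 1)
    bins: list[int] = []
    lo = start >> _FIRST_SHIFT
    hi = (end - 1) >> _FIRST_SHIFT
    for offset in _BIN_OFFSETS:
        bins.extend(range(offset + lo, offset + hi + 1))
        lo >>= _NEXT_SHIFT
        hi >>= _NEXT_SHIFT
    return bins


def _serialize(iv: GenomicInterval) -> str:
    return json.dumps(
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "strand": iv.strand,
            "exons": iv.exons,
            "name": iv.name,
            "tags": iv.tags,
        },
        separators=(",", ":"),
    )


def _deserialize(payload: str) -> GenomicInterval:
    d = json.loads(payload)
    d["exons"] = [tuple(e) for e in d["exons"]]
    return GenomicInterval(**d)


class IntervalStore:
    """Multiset of :class:`GenomicInterval` with indexed overlap queries.

    A store is a single SQLite file (or fully in-memory with the default
    path ``":memory:"``); a B-tree index on ``(chrom, bin)`` makes bin
    lookups sublinear in table size.
    """

    def __init__(self, path: str = ":memory:"):
        self.path = path
        self._conn = sqlite3.connect(path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS intervals ("
            " id INTEGER PRIMARY KEY,"
            " chrom TEXT NOT NULL,"
            " bin INTEGER NOT NULL,"
            " start INTEGER NOT NULL,"
            " end INTEGER NOT NULL,"
            " payload TEXT NOT NULL)"
        )
        self._conn.execute(
            "CREATE INDEX IF NOT EXISTS idx_chrom_bin"
            " ON intervals (chrom, bin)"
        )

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], path: str = ":memory:"
    ) -> "IntervalStore":
        store = cls(path)
        store.insert_many(intervals)
        return store

    def insert(self, interval: GenomicInterval) -> None:
        self.insert_many([interval])

    def insert_many(self, intervals: Iterable[GenomicInterval]) -> None:
        rows = (
            (iv.chrom, bin_of(iv.start, iv.end), iv.start, iv.end,
             _serialize(iv))
            for iv in intervals
        )
        with self._conn:
            self._conn.executemany(
                "INSERT INTO intervals (chrom, bin, start, end, payload)"
                " VALUES (?, ?, ?, ?, ?)",
                rows,
            )

    def query(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        """Stored intervals whose footprint intersects ``[start, end)``.

        Results are ordered by ascending ``(start, end)``.  An unknown
        chromosome yields an empty list.
        """
        bins = bins_for_range(start, end)
        placeholders = ",".join("?" * len(bins))
        cur = self._conn.execute(
            f"SELECT payload FROM intervals"
            f" WHERE chrom = ? AND bin IN ({placeholders})"
            f" AND start < ? AND end > ?"
            f" ORDER BY start, end",
            [chrom, *bins, end, start],
        )
        return [_deserialize(row[0]) for row in cur]

    def chromosomes(self) -> list[str]:
        cur = self._conn.execute(
            "SELECT DISTINCT chrom FROM intervals ORDER BY chrom"
        )
        return [row[0] for row in cur]

    def __iter__(self) -> Iterator[GenomicInterval]:
        cur = self._conn.execute(
            "SELECT payload FROM intervals ORDER BY chrom, start, end"
        )
        for (payload,) in cur:
            yield _deserialize(payload)

    def __len__(self) -> int:
        (n,) = self._conn.execute("SELECT COUNT(*) FROM intervals").fetchone()
        return n

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "IntervalStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
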