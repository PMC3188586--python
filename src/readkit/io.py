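"""Readers and writers bridging standard formats to :class:`GenomicInterval`.

Supported inputs: SAM (plain text, header optional), BED 3/6/12, GFF3, a
column-mapped generic tabular mapper format (covering BLAST -m 8 style
dialects), and FASTA for read sequences.  Supported outputs: GFF3 (the
default annotation format), BED12, SAM-like text and spreadsheet CSV.

Every reader yields intervals lazily (streaming) and converts the format's
coordinate convention to the internal 0-based half-open one at the
boundary.  Parse failures report the offending line number.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

from .model import (
    STRAND_FWD,
    merge_blocks,
    STRAND_NONE,
    STRAND_REV,
    TAG_HITS,
    TAG_MISMATCHES,
    GenomicInterval,
)


class ParseError(ValueError):
    def __init__(self, path: str, line_number: int, message: str):
        super().__init__(f"{path}:{line_number}: {message}")
        self.path = path
        self.line_number = line_number


# ---------------------------------------------------------------------------
# SAM

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_SAM_TAG_CASTS = {"i": int, "f": float}


def cigar_to_exons(pos: int, cigar: str) -> list[tuple[int, int]]:
    """Walk a CIGAR string into reference exons starting at 0-based ``pos``.

    M/=/X and D consume reference within the current exon; N (intron)
    closes the exon and opens the next; I/S/H/P consume no reference.
    """
    if not cigar or cigar == "*":
        raise ValueError("missing CIGAR")
    if "".join(f"{n}{op}" for n, op in _CIGAR_RE.findall(cigar)) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    exons: list[tuple[int, int]] = []
    ref = pos
    exon_start = pos
    for length, op in _CIGAR_RE.findall(cigar):
        n = int(length)
        if op in "M=XD":
            ref += n
        elif op == "N":
            if ref > exon_start:
                exons.append((exon_start, ref))
            ref += n
            exon_start = ref
        # I, S, H, P: no reference consumed
    if ref > exon_start:
        exons.append((exon_start, ref))
    if not exons:
        raise ValueError(f"CIGAR {cigar!r} consumes no reference")
    return exons


def read_sam(path: str) -> Iterator[GenomicInterval]:
    """Stream mapped records from a plain-text SAM file.

    Unmapped records (FLAG 0x4 or RNAME ``*``) are skipped.  POS is
    converted from 1-based; N operators split exons so spliced long reads
    keep their intron structure.  NH maps to the hit-count tag, NM to the
    mismatch tag; any other optional field is preserved verbatim.
    """
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(path, ln, "fewer than 11 SAM columns")
            qname, flag_s, rname, pos_s, _mapq, cigar = fields[:6]
            try:
                flag = int(flag_s)
                pos = int(pos_s)
            except ValueError:
                raise ParseError(path, ln, "non-numeric FLAG/POS") from None
            if flag & 0x4 or rname == "*":
                continue
            try:
                exons = cigar_to_exons(pos - 1, cigar)
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None
            tags: dict = {}
            for opt in fields[11:]:
                parts = opt.split(":", 2)
                if len(parts) != 3:
                    raise ParseError(path, ln, f"malformed tag {opt!r}")
                tag, typ, val = parts
                value = _SAM_TAG_CASTS.get(typ, str)(val)
                if tag == "NH":
                    tags[TAG_HITS] = int(value)
                elif tag == "NM":
                    tags[TAG_MISMATCHES] = int(value)
                else:
                    tags[tag] = value
            yield GenomicInterval(
                chrom=rname,
                start=exons[0][0],
                end=exons[-1][1],
                strand=STRAND_REV if flag & 0x10 else STRAND_FWD,
                exons=exons if len(exons) > 1 else [],
                name=qname,
                tags=tags,
            )


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str) -> Iterator[GenomicInterval]:
    """Stream BED3/BED6/BED12 records (already 0-based half-open)."""
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(path, ln, "fewer than 3 BED columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except ValueError:
                raise ParseError(path, ln, "non-numeric coordinates") from None
            name = f[3] if len(f) > 3 else ""
            strand = STRAND_NONE
            if len(f) > 5 and f[5] in (STRAND_FWD, STRAND_REV):
                strand = f[5]
            exons: list[tuple[int, int]] = []
            if len(f) >= 12:
                try:
                    n_blocks = int(f[9])
                    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                    starts = [int(x) for x in f[11].rstrip(",").split(",")]
                except ValueError:
                    raise ParseError(path, ln, "malformed block columns") from None
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise ParseError(
                        path, ln, "blockCount disagrees with block lists"
                    )
                exons = [(start + o, start + o + s)
                         for o, s in zip(starts, sizes)]
                if len(exons) == 1:
                    exons = []
            try:
                yield GenomicInterval(chrom, start, end, strand,
                                      exons=exons, name=name)
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None


# ---------------------------------------------------------------------------
# GFF3

def _parse_gff_attributes(col: str, path: str, ln: int) -> dict:
    tags: dict = {}
    for item in col.rstrip(";").split(";"):
        if not item:
            continue
        if "=" not in item:
            raise ParseError(path, ln, f"malformed attribute {item!r}")
        key, value = item.split("=", 1)
        tags[key.strip()] = value.strip()
    return tags


def read_gff3(path: str) -> Iterator[GenomicInterval]:
    """Read GFF3 features, assembling children that share a Parent.

    Features whose ``Parent`` matches the ID of another feature are folded
    into one multi-exon interval named by the parent ID; parentless
    features become single-exon intervals.  A child whose parent line
    never appears is emitted standalone.  1-based inclusive coordinates
    are shifted to the internal convention.
    """
    import warnings

    known_ids: set[str] = set()
    # child blocks grouped by Parent, remembering chrom/strand
    children: dict[str, list[tuple[str, str, int, int]]] = {}
    order: list[GenomicInterval | str] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ParseError(path, ln, "expected 9 GFF3 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = f
            try:
                start, end = int(start_s) - 1, int(end_s)
            except ValueError:
                raise ParseError(path, ln, "non-numeric coordinates") from None
            tags = _parse_gff_attributes(attrs, path, ln)
            strand = strand if strand in (STRAND_FWD, STRAND_REV) else STRAND_NONE
            parent = tags.get("Parent")
            if parent is not None:
                if parent not in children:
                    order.append(parent)  # placeholder, resolved at flush
                children.setdefault(parent, []).append(
                    (chrom, strand, start, end)
                )
                continue
            try:
                iv = GenomicInterval(chrom, start, end, strand,
                                     name=tags.get("ID", ""),
                                     tags={"type": ftype, **tags})
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None
            ident = tags.get("ID")
            if ident is not None:
                known_ids.add(ident)
            order.append(iv)

    for item in order:
        if isinstance(item, GenomicInterval):
            ident = item.tags.get("ID")
            rows = children.pop(ident, None) if ident else None
            if rows:
                blocks = merge_blocks(
                    ((s, e) for _c, _st, s, e in rows), max_gap=-1
                )
                item.start = min(item.start, blocks[0][0])
                item.end = max(item.end, blocks[-1][1])
                item.exons = blocks if len(blocks) > 1 else []
            yield item
        elif item in children and item not in known_ids:
            # parent line never appeared: emit the assembled child standalone
            warnings.warn(f"{path}: Parent {item!r} never defined")
            rows = children.pop(item)
            blocks = merge_blocks(
                ((s, e) for _c, _st, s, e in rows), max_gap=-1
            )
            yield GenomicInterval(
                rows[0][0], blocks[0][0], blocks[-1][1], rows[0][1],
                exons=blocks if len(blocks) > 1 else [], name=item,
            )


# ---------------------------------------------------------------------------
# Generic tabular mapper output

@dataclass
class TabularSpec:
    """Column mapping for a tab-separated mapper dialect.

    Column indices are 0-based.  ``one_based``/``inclusive_end`` describe
    the dialect's coordinate convention; ``strand_from_coords`` infers a
    minus strand from reversed start/end (BLAST style).  ``hits_col``
    optionally carries the per-read genomic hit count.
    """

    chrom_col: int
    start_col: int
    end_col: int
    strand_col: Optional[int] = None
    name_col: Optional[int] = None
    hits_col: Optional[int] = None
    one_based: bool = False
    inclusive_end: bool = False
    strand_from_coords: bool = False


#: BLAST -m 8: query, subject, %id, length, mm, gaps, qs, qe, ss, se, e, bits
BLAST_M8 = TabularSpec(
    chrom_col=1, start_col=8, end_col=9, name_col=0,
    one_based=True, inclusive_end=True, strand_from_coords=True,
)


def read_tabular(path: str, spec: TabularSpec) -> Iterator[GenomicInterval]:
    """Stream a column-mapped tab-separated mapping file."""
    needed = max(
        c for c in (spec.chrom_col, spec.start_col, spec.end_col,
                    spec.strand_col, spec.name_col, spec.hits_col)
        if c is not None
    )
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) <= needed:
                raise ParseError(
                    path, ln, f"expected at least {needed + 1} columns"
                )
            try:
                start = int(f[spec.start_col])
                end = int(f[spec.end_col])
            except ValueError:
                raise ParseError(path, ln, "non-numeric coordinates") from None
            strand = STRAND_NONE
            if spec.strand_from_coords and start > end:
                start, end = end, start
                strand = STRAND_REV
            elif spec.strand_from_coords:
                strand = STRAND_FWD
            if spec.strand_col is not None:
                raw = f[spec.strand_col]
                strand = raw if raw in (STRAND_FWD, STRAND_REV) else STRAND_NONE
            if spec.one_based:
                start -= 1
                if not spec.inclusive_end:
                    end -= 1
            elif spec.inclusive_end:
                end += 1
            tags = {}
            if spec.hits_col is not None:
                try:
                    tags[TAG_HITS] = int(f[spec.hits_col])
                except ValueError:
                    raise ParseError(path, ln, "non-numeric hit count") from None
            try:
                yield GenomicInterval(
                    f[spec.chrom_col], start, end, strand,
                    name=f[spec.name_col] if spec.name_col is not None else "",
                    tags=tags,
                )
            except ValueError as exc:
                raise ParseError(path, ln, str(exc)) from None


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str) -> Iterator[tuple[str, str]]:
    """Yield (name, sequence) pairs; U is mapped to T."""
    for record in SeqIO.parse(path, "fasta"):
        yield record.id, str(record.seq).upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Writers

def write_gff3(records: Iterable[GenomicInterval], path: str,
               source: str = "readkit") -> None:
    """Write GFF3: a ``match`` parent plus ``match_part`` children for
    multi-exon records; coordinates restored to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, iv in enumerate(records):
            ident = iv.name or f"record_{i + 1}"
            attrs = [f"ID={ident}"]
            for key, value in iv.tags.items():
                if key not in ("ID", "Parent"):
                    attrs.append(f"{key}={value}")
            fh.write(
                f"{iv.chrom}\t{source}\tmatch\t{iv.start + 1}\t{iv.end}\t."
                f"\t{iv.strand}\t.\t{';'.join(attrs)}\n"
            )
            if len(iv.exon_blocks) > 1:
                for j, (s, e) in enumerate(iv.exon_blocks, 1):
                    fh.write(
                        f"{iv.chrom}\t{source}\tmatch_part\t{s + 1}\t{e}\t."
                        f"\t{iv.strand}\t.\tID={ident}.{j};Parent={ident}\n"
                    )


def write_bed(records: Iterable[GenomicInterval], path: str) -> None:
    """Write BED12 (block columns carry the exon structure)."""
    with open(path, "w") as fh:
        for i, iv in enumerate(records):
            blocks = iv.exon_blocks
            sizes = ",".join(str(e - s) for s, e in blocks)
            starts = ",".join(str(s - iv.start) for s, e in blocks)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{iv.name or f'record_{i + 1}'}\t0\t{iv.strand}\t"
                f"{iv.start}\t{iv.end}\t0\t{len(blocks)}\t{sizes}\t{starts}\n"
            )


def write_sam(records: Iterable[GenomicInterval], path: str,
              chrom_sizes: Optional[dict[str, int]] = None) -> None:
    """Write a minimal SAM-like text file (no sequences, ``*`` fields)."""
    records = list(records)
    if chrom_sizes is None:
        chrom_sizes = {}
        for iv in records:
            chrom_sizes[iv.chrom] = max(chrom_sizes.get(iv.chrom, 0), iv.end)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom in sorted(chrom_sizes):
            fh.write(f"@SQ\tSN:{chrom}\tLN:{chrom_sizes[chrom]}\n")
        for i, iv in enumerate(records):
            flag = 16 if iv.strand == STRAND_REV else 0
            cigar_parts = []
            prev_end = None
            for s, e in iv.exon_blocks:
                if prev_end is not None:
                    cigar_parts.append(f"{s - prev_end}N")
                cigar_parts.append(f"{e - s}M")
                prev_end = e
            opts = []
            if TAG_HITS in iv.tags:
                opts.append(f"NH:i:{iv.tags[TAG_HITS]}")
            if TAG_MISMATCHES in iv.tags:
                opts.append(f"NM:i:{iv.tags[TAG_MISMATCHES]}")
            line = (
                f"{iv.name or f'read_{i + 1}'}\t{flag}\t{iv.chrom}\t"
                f"{iv.start + 1}\t255\t{''.join(cigar_parts)}\t*\t0\t0\t*\t*"
            )
            if opts:
                line += "\t" + "\t".join(opts)
            fh.write(line + "\n")


def write_csv(records: Iterable[GenomicInterval], path: str) -> None:
    """Spreadsheet export: one row per record, tags expanded to columns."""
    records = list(records)
    tag_keys: list[str] = []
    for iv in records:
        for key in iv.tags:
            if key not in tag_keys:
                tag_keys.append(key)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["name", "chrom", "start", "end", "strand", "size", "nExons"]
            + tag_keys
        )
        for iv in records:
            writer.writerow(
                [iv.name, iv.chrom, iv.start, iv.end, iv.strand, iv.size,
                 iv.n_exons]
                + [iv.tags.get(k, "") for k in tag_keys]
            )


_READERS = {"sam": read_sam, "bed": read_bed, "gff3": read_gff3}
_WRITERS = {"gff3": write_gff3, "bed": write_bed, "sam": write_sam,
            "csv": write_csv}


def read_any(path: str, fmt: str) -> Iterator[GenomicInterval]:
    try:
        return _READERS[fmt.lower()](path)
    except KeyError:
        raise ValueError(f"unknown input format {fmt!r}") from None


def write_any(records: Iterable[GenomicInterval], path: str, fmt: str) -> None:
    try:
        _WRITERS[fmt.lower()](records, path)
    except KeyError:
        raise ValueError(f"unknown output format {fmt!r}") from None


def convert(in_path: str, out_path: str, from_fmt: str, to_fmt: str) -> int:
    """Convert between formats; returns the number of records written."""
    records = list(read_any(in_path, from_fmt))
    write_any(records, out_path, to_fmt)
    return len(records)
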