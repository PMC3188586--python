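"""Synthetic mapped-read fixtures with planted structure.

The generator emulates a small-RNA sequencing experiment after mapping:
clusters of 28-30 nt reads (the piRNA size class) planted at known loci,
decoy clusters that legitimate filters should remove (too few reads, or
multi-mappers only), and a scatter of background reads.  Multi-mappers are
emitted once per genomic placement with an NH tag > 1, extra placements
landing in a dedicated repeat region.  A truth table records every planted
locus so recovery can be scored exactly.

It also simulates two-condition count data (per-region Poisson reads with
planted fold changes) for exercising the differential-expression tests.

Everything is driven by a single integer seed; identical seeds give
byte-identical output files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    STRAND_FWD,
    STRAND_REV,
    TAG_HITS,
    TAG_MISMATCHES,
    GenomicInterval,
)
from .io import write_gff3, write_sam


@dataclass
class FixtureSpec:
    """Parameters of the planted-cluster read fixture.

    Defaults describe a compact but realistic small-RNA experiment: two
    chromosomes of a few hundred kb, five genuine piRNA-like clusters of
    10-40 reads spanning 1-5 kb each, three under-populated decoy clusters
    and one multi-mapper-only decoy, read sizes 26-32 nt with the 28-30 nt
    core enriched, and sparse non-overlapping background reads.
    """

    seed: int = 0
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chr1", 500_000), ("chr2", 400_000)]
    )
    n_clusters: int = 5
    cluster_reads: tuple[int, int] = (12, 40)   # planted cluster occupancy
    cluster_span: tuple[int, int] = (1_000, 5_000)
    n_small_decoys: int = 3                     # < min_elements reads each
    small_decoy_reads: tuple[int, int] = (3, 8)
    n_multimapper_decoys: int = 1               # no unique mapper inside
    read_size_range: tuple[int, int] = (26, 32)
    core_size_range: tuple[int, int] = (28, 30)
    core_fraction: float = 0.8                  # reads drawn from the core
    fraction_multi_mappers: float = 0.2
    n_background_reads: int = 200

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if self.cluster_span[1] > length:
                raise ValueError(
                    f"cluster span {self.cluster_span[1]} exceeds {name}"
                )


@dataclass
class Fixture:
    reads: list[GenomicInterval]
    annotation: list[GenomicInterval]
    truth: list[dict]
    spec: FixtureSpec


def _core_size(rng: np.random.Generator, spec: FixtureSpec) -> int:
    return int(rng.integers(spec.core_size_range[0],
                            spec.core_size_range[1] + 1))


def _offcore_size(rng: np.random.Generator, spec: FixtureSpec) -> int:
    """A size inside the read range but outside the enriched core."""
    lo, hi = spec.read_size_range
    clo, chi = spec.core_size_range
    choices = [s for s in range(lo, hi + 1) if s < clo or s > chi]
    if not choices:
        return _core_size(rng, spec)
    return int(choices[rng.integers(0, len(choices))])


def _draw_size(rng: np.random.Generator, spec: FixtureSpec) -> int:
    if rng.random() < spec.core_fraction:
        return _core_size(rng, spec)
    lo, hi = spec.read_size_range
    return int(rng.integers(lo, hi + 1))


def _cluster_reads(
    rng: np.random.Generator,
    spec: FixtureSpec,
    chrom: str,
    base: int,
    n_reads: int,
    strand: str,
    name_prefix: str,
    multi_only: bool,
    repeat_sites: list[tuple[str, int]],
) -> tuple[list[GenomicInterval], tuple[int, int]]:
    """Reads of one planted locus, plus its core footprint.

    Core-size reads are laid as an overlap chain (each start at most 12 nt
    past the previous, shorter than any read), so the locus stays one
    single-linkage cluster even after the off-core sizes are filtered
    away.  Off-core reads fall anywhere within the chain's extent.
    """
    n_core = max(1, -(-n_reads * 8 // 10))  # ceil(0.8 n)
    n_offcore = n_reads - n_core
    reads: list[GenomicInterval] = []
    idx = 0

    def emit(pos: int, size: int, multi: bool) -> None:
        nonlocal idx
        idx += 1
        n_hits = int(rng.integers(2, 5)) if multi else 1
        tags = {TAG_HITS: n_hits, TAG_MISMATCHES: int(rng.random() < 0.1)}
        name = f"{name_prefix}_read{idx}"
        reads.append(
            GenomicInterval(chrom, pos, pos + size, strand,
                            name=name, tags=dict(tags))
        )
        # extra placements of a multi-mapper land in the repeat region
        for j in range(n_hits - 1):
            rchrom, rpos = repeat_sites[
                int(rng.integers(0, len(repeat_sites)))
            ]
            reads.append(
                GenomicInterval(rchrom, rpos + j * 40,
                                rpos + j * 40 + size, strand,
                                name=name, tags=dict(tags))
            )

    pos = base
    footprint_end = base
    for i in range(n_core):
        size = _core_size(rng, spec)
        # the first member stays unique unless the locus is a pure
        # multi-mapper decoy
        multi = multi_only or (
            i > 0 and rng.random() < spec.fraction_multi_mappers
        )
        emit(pos, size, multi)
        footprint_end = max(footprint_end, pos + size)
        pos += int(rng.integers(5, 13))
    footprint = (base, footprint_end)
    for _ in range(n_offcore):
        size = _offcore_size(rng, spec)
        lo, hi = base, max(base + 1, footprint_end - size)
        emit(int(rng.integers(lo, hi)), size, multi_only)
    return reads, footprint


def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Build the planted-cluster fixture in memory (see module docstring).

    Planted and decoy loci are laid out on non-overlapping slots separated
    by at least 10 kb; background reads sit on a jittered grid so no two
    of them overlap (they can never form a spurious cluster).
    """
    rng = np.random.default_rng(spec.seed)
    chrom_names = [c for c, _l in spec.chromosomes]
    chrom_len = dict(spec.chromosomes)

    # reserve the tail of the last chromosome as the multi-mapper repeat zone
    repeat_chrom = chrom_names[-1]
    repeat_zone = chrom_len[repeat_chrom] - 50_000
    repeat_sites = [
        (repeat_chrom, repeat_zone + k * 500) for k in range(40)
    ]

    n_loci = spec.n_clusters + spec.n_small_decoys + spec.n_multimapper_decoys
    slots: list[tuple[str, int]] = []
    per_chrom = -(-n_loci // len(chrom_names))  # ceil
    for chrom in chrom_names:
        usable = chrom_len[chrom] - 60_000  # keep clear of the repeat zone
        step = usable // (per_chrom + 1)
        for k in range(per_chrom):
            slots.append((chrom, 10_000 + k * step))
    rng.shuffle(slots)

    reads: list[GenomicInterval] = []
    truth: list[dict] = []
    slot_iter = iter(slots)

    def plant(kind: str, index: int, n_reads: int, multi_only: bool):
        chrom, base = next(slot_iter)
        strand = STRAND_FWD if rng.random() < 0.5 else STRAND_REV
        prefix = f"{kind}{index}"
        cluster_reads, footprint = _cluster_reads(
            rng, spec, chrom, base, n_reads, strand, prefix,
            multi_only, repeat_sites,
        )
        reads.extend(cluster_reads)
        truth.append(
            {
                "name": prefix,
                "kind": kind,
                "chrom": chrom,
                "start": footprint[0],
                "end": footprint[1],
                "strand": strand,
                "n_reads": n_reads,
                "qualifying": kind == "planted",
            }
        )

    for i in range(spec.n_clusters):
        n_reads = int(rng.integers(*spec.cluster_reads))
        plant("planted", i + 1, n_reads, multi_only=False)
    for i in range(spec.n_small_decoys):
        n_reads = int(rng.integers(*spec.small_decoy_reads))
        plant("smalldecoy", i + 1, n_reads, multi_only=False)
    for i in range(spec.n_multimapper_decoys):
        n_reads = int(rng.integers(*spec.cluster_reads))
        plant("multidecoy", i + 1, n_reads, multi_only=True)

    # background: jittered grid, guaranteed non-overlapping, first
    # chromosome; kept clear of planted loci so it can neither extend a
    # planted footprint nor rescue a decoy
    bg_chrom = chrom_names[0]
    keepout = [
        (t["start"] - 200, t["end"] + 200)
        for t in truth
        if t["chrom"] == bg_chrom
    ]
    grid = (chrom_len[bg_chrom] - 20_000) // max(1, spec.n_background_reads)
    for i in range(spec.n_background_reads):
        size = _draw_size(rng, spec)
        pos = 10_000 + i * grid + int(rng.integers(0, max(1, grid - 40)))
        if any(pos < ke and pos + size > ks for ks, ke in keepout):
            continue
        strand = STRAND_FWD if rng.random() < 0.5 else STRAND_REV
        reads.append(
            GenomicInterval(
                bg_chrom, pos, pos + size, strand,
                name=f"bg_read{i + 1}",
                tags={TAG_HITS: 1, TAG_MISMATCHES: 0},
            )
        )

    annotation = [
        GenomicInterval(
            t["chrom"], t["start"], t["end"], t["strand"], name=t["name"]
        )
        for t in truth
    ]
    return Fixture(reads=reads, annotation=annotation, truth=truth, spec=spec)


def write_fixture(fixture: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write reads.sam, annotation.gff3 and truth.csv; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.sam",
        "annotation": outdir / "annotation.gff3",
        "truth": outdir / "truth.csv",
    }
    write_sam(fixture.reads, str(paths["reads"]),
              chrom_sizes=dict(fixture.spec.chromosomes))
    write_gff3(fixture.annotation, str(paths["annotation"]))
    with open(paths["truth"], "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(fixture.truth[0]))
        writer.writeheader()
        writer.writerows(fixture.truth)
    return paths


# ---------------------------------------------------------------------------
# Two-condition simulations for differential expression

def simulate_two_condition_reads(
    rng: np.random.Generator,
    gene_lengths: list[int],
    rate_per_nt_a: float,
    rate_per_nt_b: float,
    chrom: str = "chr1",
    gap: int = 1000,
    read_size: int = 30,
) -> tuple[list[GenomicInterval], list[GenomicInterval], list[GenomicInterval]]:
    """Poisson reads over tandem genes at per-nucleotide rates.

    Genes are laid head-to-tail with ``gap`` nt spacers; each gene g of
    length L receives Poisson(L * rate) reads per condition, placed
    uniformly within the gene body.  Returns (reads_a, reads_b, genes).
    """
    genes: list[GenomicInterval] = []
    pos = gap
    for i, length in enumerate(gene_lengths):
        genes.append(
            GenomicInterval(chrom, pos, pos + length, STRAND_FWD,
                            name=f"gene_{i + 1}")
        )
        pos += length + gap
    conditions = []
    for rate in (rate_per_nt_a, rate_per_nt_b):
        reads: list[GenomicInterval] = []
        for gene in genes:
            length = gene.end - gene.start
            n = int(rng.poisson(length * rate))
            if n == 0:
                continue
            starts = rng.integers(gene.start,
                                  max(gene.start + 1, gene.end - read_size),
                                  size=n)
            for j, s in enumerate(starts):
                reads.append(
                    GenomicInterval(
                        chrom, int(s), int(s) + read_size, STRAND_FWD,
                        name=f"{gene.name}_r{len(reads)}",
                        tags={TAG_HITS: 1},
                    )
                )
        conditions.append(reads)
    return conditions[0], conditions[1], genes


def simulate_null_counts(
    rng: np.random.Generator, n_regions: int, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """Equal-rate Poisson counts for two conditions (no true signal)."""
    return (
        rng.poisson(rate, size=n_regions).astype(float),
        rng.poisson(rate, size=n_regions).astype(float),
    )
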