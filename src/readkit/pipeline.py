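"""End-to-end piRNA cluster discovery pipeline.

Chains the toolbox primitives into the canonical small-RNA workflow:
keep reads of the piRNA size class (28-30 nt), merge overlapping reads
into strand-specific clusters, keep clusters with at least 10 reads, then
rescue only clusters containing at least one uniquely mapping read (a
cluster made solely of multi-mappers cannot be confidently placed), and
finally plot the cluster density along the chromosomes and export the
cluster list as GFF3 plus a spreadsheet CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .model import Cluster, GenomicInterval
from .io import write_csv, write_gff3
from .ops import FilterSpec, clusterize, filter_by_size, filter_by_tags, \
    filter_clusters
from .profiles import density_profile, render_plot

logger = logging.getLogger("readkit.pipeline")


@dataclass
class PipelineResult:
    clusters: list[Cluster]
    stage_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, Path] = field(default_factory=dict)


def pirna_pipeline(
    reads: Sequence[GenomicInterval],
    min_size: int = 28,
    max_size: int = 30,
    min_elements: int = 10,
    require_unique_mapper: bool = True,
    max_distance: int = 0,
    strand_specific: bool = True,
    density_bin_size: int = 100_000,
    outdir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run the piRNA cluster discovery workflow on mapped reads.

    Stage record counts are logged (one line per stage) and returned; when
    ``outdir`` is given the surviving clusters are written as
    ``clusters.gff3`` and ``clusters.csv`` together with a per-chromosome
    density table/plot.
    """
    counts: dict[str, int] = {}

    def log(stage: str, n_in: int, n_out: int) -> None:
        counts[stage] = n_out
        logger.info("%s: in=%d out=%d", stage, n_in, n_out)

    reads = list(reads)
    counts["input"] = len(reads)

    sized = filter_by_size(reads, min_size, max_size)
    log("size_filter", len(reads), len(sized))

    clusters = clusterize(sized, max_distance=max_distance,
                          strand_specific=strand_specific)
    log("clusterize", len(sized), len(clusters))

    populous = filter_clusters(clusters, min_elements=min_elements)
    log("min_elements_filter", len(clusters), len(populous))

    unique = filter_by_tags(sized, FilterSpec(exact_hits=1))
    log("unique_mappers", len(sized), len(unique.records))

    if require_unique_mapper:
        rescued = filter_clusters(populous, require_unique_mapper=True)
    else:
        rescued = populous
    log("unique_mapper_rescue", len(populous), len(rescued))

    result = PipelineResult(clusters=rescued, stage_counts=counts)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        footprints = [c.interval for c in rescued]
        gff_path = outdir / "clusters.gff3"
        csv_path = outdir / "clusters.csv"
        write_gff3(footprints, str(gff_path))
        write_csv(footprints, str(csv_path))
        result.outputs["gff3"] = gff_path
        result.outputs["csv"] = csv_path
        if rescued:
            for chrom, hist in density_profile(
                footprints, density_bin_size
            ).items():
                png = outdir / f"density_{chrom}.png"
                render_plot(hist, str(png))
                result.outputs[f"density_{chrom}"] = png
    return result
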