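# Methods notes

## Coordinate model

All coordinates are 0-based half-open internally; conversion happens only
at format boundaries (GFF3 and SAM are 1-based inclusive, BED is already
half-open). One internal convention eliminates whole classes of
off-by-one errors; the readers/writers carry the burden of translation
and are covered by round-trip tests.

A read's **size** is its spliced length (sum of exon lengths), not its
genomic span. This is deliberate: size filters concern the sequenced
molecule (e.g. the 28–30 nt piRNA class), and a spliced read's span
includes introns the molecule never contained.

**Unstranded records (`.`) match both strands** in strand-specific
comparisons. A permissive default avoids silently discarding reads
against strand-unannotated references; callers who want strictness can
pre-filter.

**Overlap vs distance at adjacency.** With half-open intervals,
`[10,20)` and `[20,30)` do not overlap but have gap 0. Consequently
"distance 0" is implied by, but does not imply, overlap. Clustering with
`max_distance=0` therefore requires a shared nucleotide, not book-ended
adjacency; any positive merge window also joins book-ended reads.

The overlap test is exon-aware only on request (`exon_aware=True`):
whether a read "overlapping" an annotation should see through introns is
analysis-dependent, so both semantics are exposed and the footprint test
is the default.

## Nested-bin interval store

The store uses the standard 5-level genome partitioning: bin widths
128 kb, 1 Mb, 8 Mb, 64 Mb, 512 Mb with level offsets 585, 73, 9, 1, 0.
An interval lives in the smallest bin containing it; a query probes, per
level, the bins its range spans (ancestors plus spanned descendants) and
verifies coordinates. Coordinates past 512 Mb fall into the root bin —
correct (the root is always probed) but unindexed, a deliberate choice so
outsized scaffolds degrade gracefully instead of failing ingestion.

Storage is a single SQLite file (or `:memory:`), payloads serialized as
JSON, with a B-tree index on `(chrom, bin)`. Indexing the pair rather
than the bin alone keeps multi-chromosome tables sublinear; only the
round-trip fidelity of the payload and the index's sublinearity are
contractual, not the encodings. Concurrent writers are out of scope.

Tests check the probe bound on a 100k-record store and query equivalence
against linear-scan and interval-tree oracles on randomized instances;
the persistence test closes and reopens the file between queries.

## Format handling

SAM is parsed from text directly: the exon extraction from CIGAR (M/=/X
and D consume reference within an exon, N splits exons, I/S/H/P consume
none) is itself part of the library's contract, the header is optional,
and parse errors must report line numbers — requirements a BAM-oriented
reader does not meet. The test suite cross-checks the parser against
pysam on generated files (coordinates, blocks, strand). Unknown SAM
optional fields pass through verbatim as tags; `NH`/`NM` map to the
hit-count and mismatch tags used by the filters.

GFF3 features sharing a `Parent` are folded into one multi-exon interval
named by the parent ID; a child whose parent never appears is emitted
standalone with a warning. Because children may precede or follow their
parent, the GFF3 reader buffers pending groups; the mapped-read readers
(SAM, BED, tabular) are strictly streaming, which the memory-proxy test
asserts — those are the formats that reach millions of lines.

Eleven bespoke mapper formats are covered by one column-mapped tabular
reader with presets (BLAST `-m 8` ships; minus strand inferred from
reversed subject coordinates). Spreadsheet export is CSV: diffable,
dependency-free, opens in Excel.

The GFF3 writer emits a `match` parent plus `match_part` children for
multi-exon records, standard practice for mapped reads.

## Clustering

Single-linkage per chromosome (and per strand by default — small-RNA
clusters are strand-coherent; `strand_specific=False` disables): reads
sorted by start join the open cluster if they overlap its footprint or
trail it by at most `max_distance` nt. A "clustering window" could mean
either an inter-read gap tolerance or fixed genomic tiles; gap merging
is what `clusterize` does, and the tile view is provided separately by
`density_profile`. Cluster footprints are the union span; member exon
blocks are merged with the same gap tolerance. `nbElements` sums to the
input read count (conservation), and clustering its own footprints is a
no-op (idempotence) — both are tested.

Bidirectional patterns pair a plus and a minus cluster that either
overlap (`pattern=overlap`, double-strand transcription) or sit
head-to-head with the minus cluster at most `max_distance` nt upstream
of the plus cluster (`pattern=divergent`, putative bidirectional
promoter). The gap uses the same definition as `distance()`.

## Differential expression

Counting: a read increments every region it overlaps by ≥ 1 nt; totals
are the library read counts. The default minimum overlap for selection
operations is 1 nt — the most permissive reading, and the common toolbox
default.

Normalizations (mutually exclusive modes; mean scaling is the default as
the simplest):

1. **mean** — scale both libraries to the average of the two totals.
2. **interquartile** — rank regions by average count; scale condition B
   by the ratio of the two conditions' sums over ranks
   `⌊n/4⌋ … ⌊3n/4⌋−1`. Assumes moderately expressed regions are not
   differential. The defining property (equal IQR sums afterwards) is
   asserted to 1e-9 relative error on randomized tables.
3. **window** — replace each region's count with the mean over windows
   of width equal to the smallest region's spliced size, slid 1 nt at a
   time (a region shorter than the window contributes its single
   placement). Implemented with difference arrays, O(length + reads) per
   region. This removes the length bias by which long genes, matching
   more reads, dominate count-based significance.

The Fisher test is two-sided by probability mass: with margins fixed,
sum the hypergeometric probabilities of all tables no more probable than
the observed one (ties included with 1e-10 relative slack; if every
table qualifies the p-value is exactly 1). The pmf is computed in one
vectorized log-gamma pass over the support, which keeps the
100,000-table calibration runs in seconds; correctness is checked
against an independent pure-Python enumeration oracle and against
`scipy.stats.fisher_exact`. One-sided alternatives are available via a
flag. Fractional (normalized or window-averaged) counts are rounded
half-to-even before testing, since the hypergeometric needs integers.

FDR control is Benjamini–Hochberg (the standard reading of "FDR" in
2011-era RNA-seq practice), delegated to
`statsmodels.stats.multitest.multipletests` and verified against a
direct step-up computation; input record order is restored on return.

**Calibration caveat.** An exact test on discrete tables is
conservative: under the null its rejection rate at 0.05 is ≤ 0.05 and
in practice ~0.043–0.046 at realistic depths, approaching but never
reaching the nominal level as counts grow. The calibration check
therefore asks that the pooled rejection fraction across 200 replicates
of 500 equal-rate Poisson regions (rate 50/region, a typical small-RNA
depth) lies within the 99% binomial band of a single replicate's
fraction around 0.05 — tight enough to catch an anticonservative or
broken test, honest about the inherent conservatism.

## Profiles

Density assigns each record to the tile containing its footprint
midpoint `(start + end − 1) // 2`, so boundary-straddling records are
never double-counted. Distance distributions report the nearest
same-chromosome reference; with `strand_relative` the value is signed,
negative when the query lies 5′ of the reference in the reference's
orientation (plots can always collapse the sign; unsigned data cannot be
re-signed). Queries beyond `max_distance` or on reference-free
chromosomes are tallied separately, never silently binned.

Coverage counts every overlapping read at each exonic nucleotide
(depth), not read midpoints. TSS/TES profiles span ±`flank` nt (default
1,000) oriented 5′→3′ by feature strand; meta-gene profiles cut each
body into `n_bins` (default 100) equal bins and skip (with a tally)
features shorter than one nt per bin. A minus-strand feature's profile
is exactly the reverse of its plus-strand mirror — asserted as a
symmetry test.

Plots are rendered with matplotlib (Agg), but the CSV table written next
to every image is the contractual output; pixel appearance is not.

## Synthetic fixtures

The generator emulates a mapped small-RNA immunoprecipitation
experiment: two chromosomes (500 kb / 400 kb), five planted piRNA-like
clusters, three under-populated decoy clusters (3–8 reads) and one
decoy containing only multi-mappers, read sizes 26–32 nt with 80% drawn
from the 28–30 nt core, 20% multi-mapper probability (each multi-mapper
emitted once per placement with `NH` > 1, extra placements in a
dedicated repeat zone), and ~200 sparse background reads.

Two constructions make recovery a property of the *method* rather than
of luck, for any seed: a planted cluster's core-size reads form an
overlap chain (consecutive starts at most 12 nt apart, less than any
read length), so the locus survives size filtering as a single
single-linkage cluster; and background reads sit on a jittered grid,
pairwise non-overlapping and kept 200 nt clear of planted loci, so they
can neither form spurious clusters nor rescue a decoy. Identical seeds
give byte-identical output files.

What the fixture does **not** emulate: sequencing errors and quality
strings, soft-clipping, realistic chromosome-scale cluster density,
genome sequence composition (SAM `SEQ` fields are `*`), or biological
strand asymmetries. Passing the recovery test shows the pipeline's
logic is correct under its stated assumptions, not that the thresholds
are optimal for any particular genome.

Two-condition simulations lay genes head-to-tail with 1 kb spacers and
draw Poisson(length × rate) uniformly placed 30-nt reads per gene per
condition; the length-bias check adds 300 unchanged 1-kb background
genes so that a 2-fold shift on the test genes is genuinely
differential rather than absorbed into the library totals.

## Problem sizes and numerical choices

The randomized suites use sizes chosen to exercise the data structures
well past their corner cases while keeping the full test run in tens of
seconds: 20 store instances of 5,000 intervals × 500 queries, 10,000
interval pairs against the per-base oracle, 2,000 reads against the
union-find clustering oracle, 1,000-record format round-trips, 2,000
Fisher tables against enumeration, 200 × 500 null calibration tests, and
100 planted-fold replicates. `scripts/acceptance.py` re-runs the same
checks at the same or slightly reduced instance counts, seeded from its
`--seed` argument via `numpy.random.SeedSequence` spawning.

Ties and degenerate inputs: empty inputs yield empty outputs (never
errors) in filters and histograms; all-zero Fisher margins give p = 1;
interquartile normalization refuses < 4 regions or an empty IQR signal
in B; inverted size bounds and negative flanks raise configuration
errors; unknown chromosomes in store queries return empty lists.

## Known limitations

* Replicate-aware dispersion modelling (negative-binomial tests à la
  DESeq/edgeR) is out of scope; the Fisher test treats each condition as
  one pooled library.
* Normalizations do not compose; they are alternative modes.
* BAM/CRAM require external conversion to SAM text.
* The store supports a single writer; no concurrent ingestion.
* Meta-gene binning uses footprints, not spliced bodies, for features.
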