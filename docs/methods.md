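# Methods

## Coordinates and gene models

All internal coordinates are 0-based half-open on the genome; GTF I/O
converts the 1-based inclusive convention at the boundary. Genes are
groups of transcripts sharing a `gene_id` (annotation semantics, not
genomic overlap). Transcripts must have sorted, non-overlapping exons
with introns of at least 1 bp; records violating this are skipped with a
warning rather than aborting the run, because real annotation files
contain oddities. Coding status is taken from the annotation
(`transcript_biotype`/CDS features, or a `coding` attribute); the
classifier itself is agnostic to it.

Acceptor and donor are used in transcript orientation throughout: the
acceptor is the intron 3' splice site, the donor the intron 5' site.
On the minus strand the genomic roles flip; splice sites are stored as
boundary coordinates so that bin construction and profile extraction are
strand-mirror symmetric (verified by a reverse-complement equivariance
test).

## Event classification

Within a gene, every transcript pair is compared. The segment-inclusion
coding (sorted union of all exon boundaries; per-transcript bit-vector;
decimal value with the most-significant bit at the transcript 5' end) is
maintained as a lossless bookkeeping representation — each transcript is
exactly recoverable from its bits — while classification itself uses
geometric predicates on internal exons, which the coding determines:

* **ES** — an internal exon of one isoform absent from the other, whose
  two flanking junctions are joined directly by the other isoform and
  which no exon of the other isoform overlaps. Only single-exon
  skipping is called.
* **ME** — two non-overlapping internal exons, one per isoform, mutually
  absent, between identical flanking junctions.
* **A3SS / A5SS** — two overlapping internal exons sharing one boundary
  and differing at the other, *where the flanking junction on the
  differing side is shared* — i.e. the two boundaries are alternative
  choices for the same intron. Without the shared-flank requirement an
  intron-retention configuration would also satisfy the predicate (the
  retaining exon shares one boundary with each short exon), conflating
  classes that the event taxonomy keeps separate. Which class it is
  (3' vs 5') depends on the strand: an alternative boundary on the
  exon's acceptor side is A3SS.
* **IR** — an internal exon spanning exactly two consecutive exons of
  the other isoform plus the intron between them.
* **CNE** — an internal exon with identical boundaries, and internal, in
  every transcript whose span covers it, excluding exons whose
  boundaries coincide with any detected event's splice sites (this
  guarantees the CNE and ASE site sets are disjoint).

Events are de-duplicated across transcript pairs by (event type, sorted
splice-site coordinates), so an event discoverable from several pairs is
counted once, and an exon matching two event types against different
partners is reported under both (each type is tested against CNE
independently). Output is invariant to transcript input order.

Analysed splice sites per event: the event exon's acceptor and donor for
ES and CNE; the **longer** alternative exon's sites for A3SS/A5SS (two
distinct exons sharing a boundary cannot tie in length; a defensive
tie-break to the 5'-most exon exists and logs a warning); the
retained-intron 5' (donor) and 3' (acceptor) boundaries for IR; and both
exons' sites, counted independently, for ME (it is unknowable which exon
a given cell includes).

The positional filter removes events whose defining exon overlaps the
first or last 2000 bp (configurable) of an evidence transcript's genomic
span, insulating the statistics from TSS/PolyA chromatin gradients. An
exon-ordinal stratifier (e.g. restrict to 2nd–4th exons) supports the
positional-control analysis.

## Signal tracks

Three track kinds share one query surface (per-region level; per-bp
values):

* **sequence CpG** — CpG dinucleotides counted directly from the genome
  (case-insensitive, N never matches). CpG is its own reverse
  complement, so counts are strand-symmetric.
* **methylation** — calls on either strand of a CpG are merged onto the
  +-strand C coordinate as one functional site; a site is methylated if
  any merged call is. The region statistic is the percentage of sites
  methylated, undefined (excluded, not imputed) when a bin has no
  sites — a percentage of nothing carries no information. When an
  upstream source provides fractional calls, any value above zero
  counts as methylated; this binarisation is a declared convention.
* **reads** — BED6 alignments extended to 200 bp along their strand
  (default; configurable), clamped at the chromosome start, never
  deduplicated (raw-read counting). Region level is the number of
  extended reads overlapping the region by ≥ 1 bp; per-bp coverage uses
  the same overlap rule. Queries run on sorted start/end arrays with
  binary search and are validated exactly against brute-force loops.

## Bins, profiles, smoothing

Each splice site gets one exonic and one intronic 100-bp bin anchored at
the boundary (bin length 50 reproduces the ±50-nt robustness variant).
Exons shorter than 200 bp make the two exonic bins of a site pair
overlap; both are kept, as sites are treated independently and extreme
exon lengths are rare. One observation = one (splice site, bin,
feature, cell line) value.

Metaprofiles cover offsets −500..+200 around acceptors and −200..+500
around donors, oriented 5'→3' (offset 0 is the first exonic base at an
acceptor, the first intronic base at a donor; minus-strand windows are
mirrored). Read profiles are mean coverage; CpG and methylation
profiles are the percentage of sites carrying the mark at each offset,
smoothed by a centred 147-bp moving average (truncated at the edges) —
147 bp being a typical exon length. Read profiles are left unsmoothed
because the 200-bp extension already smooths them. Multiple cell lines
are averaged with equal weight.

## Association testing

Per (feature, event type, bin) cell, ASE observations pooled over all
cell lines are compared with the pooled CNE observations using Welch's
unequal-variance *t*; the tail is chosen post hoc from the observed mean
difference and the reported *p* is one-tailed in that direction (exact
ties report *p* = 0.5 with direction fixed to higher-in-CNE). Welch
rather than pooled variance because the two groups are guaranteed
unequal in size (CNE vastly outnumbers any event type) and often in
variance. Pooling across cell lines means a direction consistent across
lines sharpens the *p*-value while an inconsistent one dilutes it —
deliberately, as cross-line consistency is the evidence of interest.

Two calibration facts, both verified by simulation in the test suite:
the probability of a false directional claim against the one-sided null
is the nominal α (the type-I error proper of a one-tailed test), while
the probability that *some* direction reaches *p* < α is 2α by
construction of the post-hoc tail choice. Consumers comparing many
cells should rely on the Bonferroni-adjusted values, for which the
family is, by default, every populated cell of the run (features × 5
event types × 4 bins); the family size is logged, recorded per row and
configurable. Significance is adjusted *p* < 10⁻², strictly.

Corrections are applied to the per-bin observations before testing (and
per position before profiling): ChIP input is subtracted with negatives
preserved (many splice sites genuinely have less signal than input);
nucleosome occupancy divides the signal with a pseudocount (default 1
read) guarding empty bins. A zero input track is exactly a no-op, and a
constant nucleosome track leaves every *p*-value unchanged (scale
invariance of *t*) — both are regression-tested contracts.

The signed matrix stores −log₁₀ *p* for ASE-elevated cells and +log₁₀
*p* for CNE-elevated ones (base 10 is a display choice; any base only
rescales). Cells that could not be tested are missing, and imputed to 0
("no evidence either way") only for clustering.

## Clustering and embedding

Feature rows are clustered by Lloyd k-means under Euclidean geometry
(scikit-learn backend), 25 seeded restarts by default, best
within-cluster sum of squares kept; k = 4 for features and k = 2 for
event types, both configurable. Running k-means directly on the signed
log-p row vectors is a deliberate simplification of an upstream recipe
that fed a Euclidean *distance matrix* to a k-means routine — an
ill-defined composition, since k-means operates on coordinates; the
intent (Euclidean geometry on the signed log-p patterns) is preserved.
Labels are canonicalised by sorting clusters on their centroid's
projection onto the data's first principal axis (ties by centroid norm),
so equal-seed reruns are label-stable; partition-level results are
invariant to row order. Degenerate inputs (all rows identical) produce
a logged warning and a seed-deterministic partition. Empty clusters
during iteration are handled by the backend's re-seeding rather than an
explicit farthest-point rule; the difference can only matter on
degenerate duplicate-point inputs.

Classical (Torgerson) MDS double-centres the squared Euclidean distance
matrix and keeps the top eigenvectors scaled by the root eigenvalues;
axes with non-positive eigenvalues are dropped with a warning, and each
axis's sign is fixed by making its largest-magnitude loading positive.
At full rank the embedding reproduces pairwise distances exactly;
truncation can only contract them.

## Synthetic data generator

The generator emulates the statistical structure of the real study
inputs, not their biology. Defaults: 147-bp internal exons (typical
exon length; comfortably longer than the 100-bp bins), 1000-bp introns
(≥ 2 bins plus slack), 2100-bp terminal exons so every internal exon
clears the 2000-bp positional filter by construction, 500-bp inter-gene
gaps, alternative-boundary shift 40 bp (keeps the short A3SS/A5SS exon
longer than a bin), strands alternating gene by gene, all genes tiled on
one chromosome. A near-TSS variant plants an exon 1500 bp from the
transcript start specifically to exercise the filter. Sequence is
uniform random ACGT (CpG density ≈ 1/16 per bp, ample sites per bin);
every genomic CpG becomes a methylome site emitted as a +/− call pair
with a shared Bernoulli state (baseline probability 0.6, overridable per
event type and bin side).

Read tracks follow an exact piecewise-constant Poisson process: rate λ
(default 0.2 reads/bp, i.e. λ·100 bp = 20 expected starts per bin)
everywhere, multiplied by the per-(feature, event type) effect inside
±500-bp windows around the planted events' splice sites — multiplicative
effects matching count-data behaviour of ChIP signal, applied uniformly
across the window (both bin sides). Strands are Bernoulli(1/2),
pre-extension read length 36 bp. Every planted effect is recorded in
the truth tables; every output is a pure function of the configuration
and seed (byte-identical reruns).

What the generator does *not* model — realistic nucleotide composition,
mappability, fragment-size distributions, splice-site motifs, correlated
marks, expression confounding — bounds what passing tests show: they
validate the pipeline's arithmetic, classification logic, calibration
and direction recovery under clean sampling assumptions, not robustness
to real-data artefacts.

## Problem sizes

The validation study uses 200 random genes for classifier–oracle
agreement, 10 genes per event type for exact planted recovery, 10⁴
null replicates (n = 50 per group) for test calibration, and 300 events
per type × 2 cell lines × 20 seeded runs (λ·100 bp = 20; multipliers
1.5 for A3SS/A5SS/IR and 0.67 for ES/ME) for planted-effect recovery —
sizes chosen so the full suite and the acceptance script each complete
in minutes on a single CPU while leaving the statistical conclusions
well-resolved.

## Known limitations

* Complex loci can admit event configurations outside the five
  predicates (multi-exon skips, nested alternatives); these are left
  unclassified rather than guessed.
* Absolute *p*-values depend on the Bonferroni family size, which is
  run-specific; cross-study comparison should use the recorded family.
* The CNE definition requires constitutive inclusion only among
  transcripts spanning the exon, so single-isoform genes contribute
  CNEs; annotation completeness therefore shapes the reference set.
* Methylation binarisation and the per-bin missing-data rule discard
  quantitative call depth.
* No sequencing-depth normalisation across cell lines: pooling raw
  counts assumes comparable library sizes, as in the underlying design.
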