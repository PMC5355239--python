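# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the spongeclip pipeline.  Default values are the
parameterization of the published analysis workflow the pipeline
implements; every one is configurable.

## Coordinates and formats

All internal coordinates are 0-based half-open on the genomic forward
strand.  GTF (1-based inclusive) is converted on read; BED and the
alignment TSV are native.  Gene regions (5'UTR / CDS / 3'UTR / intron) are
derived per transcript by splitting exons at the CDS boundaries, mirrored
on the − strand.  Non-coding transcripts are labeled `noncoding` and are
thereby excluded from 3'UTR-restricted analyses (configurable label).
Because the analysis is gene-level, a gene's 3'UTR is the merged union of
its transcripts' 3'UTR intervals; which isoform a given cluster belongs to
is not resolved.

## PAR-CLIP cluster calling

The caller is a deliberately simplified two-signal reimplementation of the
kernel-density strategy used by PARalyzer, driven by the same parameter
values (`BANDWIDTH=3`, `CONVERSION=T>C`, minimum 5 reads per group /
cluster / KDE, minimum cluster size 10 nt, ≥ 1 conversion location and
count, minimum read length 13 nt, zero non-conversion mismatches,
extend-by-read).  Byte-level equality with PARalyzer output is a
non-goal; the published parameters, not PARalyzer internals, define the
procedure.

Per read group, two Gaussian kernel mixtures (bandwidth b = 3 nt) are
evaluated on every integer position p:

- conversion density: mean over T→C events e of φ((p − e)/b)/b,
- non-conversion density: the same mean over covered, non-converted
  sense-strand T positions (one event per read per position).

Both densities are normalized by their event counts.  This is a design
choice the source parameterization leaves open: with *unnormalized* sums,
a crosslink converted in fewer than half of its covering reads could never
satisfy "conversion > non-conversion", and PAR-CLIP conversion
probabilities per read are routinely below 0.5.  Comparing normalized
densities asks where conversion evidence is *relatively* concentrated,
which is the question the likelihood comparison in the original tool
answers, and it behaves correctly across the whole conversion-rate range.

Candidate clusters are maximal runs where the conversion density strictly
exceeds the non-conversion density; with extend-by-read the run is widened
to the outermost boundaries of overlapping reads (one pass; two runs
extending to the same footprint are reported once).  The mode location is
the argmax of conversion density within the final span, leftmost on ties,
making output deterministic.  Cluster calling is invariant to read input
order.

When reads are ingested from SAM/BAM, per-read reference T positions (the
non-conversion universe) are recovered from the MD tag; from the TSV path
they are computed against a FASTA reference if one is supplied, otherwise
the caller falls back to using the group's observed conversion locations
as the T universe (a coarser but reference-free surrogate).

## Post-filters and replicate support

Three filters follow the caller, in order: (1) only clusters annotated to
3'UTRs (maximal-overlap annotation; ties broken 3UTR > CDS > 5UTR >
intron); (2) the cluster must contain a seed match whose interval
intersects the window ±3 nt around the mode location — the
interval-intersection reading of "not more than 3 bp up- or downstream" is
the most permissive one and is the default, with a start-distance mode
behind a switch; (3) 6mer sites never count.  Seed matches live in UTR
coordinates and are projected to the genome through the gene's 3'UTR
interval map before windowing.

A gene counts as a PAR-CLIP hit for a family only with filtered clusters
in at least two replicas.  Replicate concordance is additionally reported
as pairwise shared gene fractions (computed with respect to the smaller
set) and as multi-replica cluster groups with a minimum mutual overlap of
10 bp, resolved greedily left-to-right with each cluster joining at most
one group.  The configuration offers both a pairwise and a common-core
overlap criterion; for 1-D intervals the two are provably identical
(the common intersection length equals the minimum pairwise overlap), so
the switch exists for interface completeness and a property test asserts
the equivalence.

## Differential expression

The DE engine is intentionally minimal: the scientific content of the
pipeline lies in the thresholds and the intersection, not in the test.
Genes pass the expression filter when cpm (counts per million, raw library
sizes) exceeds 10 in strictly more than two samples.  Libraries are
normalized with TMM factors (log-ratio trim 30%, abundance trim 5%,
unweighted, reference sample chosen by upper-quartile proximity to the
mean); the implementation reproduces the Bioconductor reference
implementation to < 1e-6 on a frozen matrix (doWeighting=FALSE).  Per-gene
log2-cpm uses a prior count of 0.5 on effective library sizes.  The test
is a two-sample moderated t: residual variances are shrunk toward a prior
estimated by moment matching on log sample variances (digamma/trigamma
moments, Newton inversion of the trigamma), t is referenced to the
augmented degrees of freedom, p-values are two-sided, and BH adjustment is
applied across all tested genes.

Calibration on negative-binomial simulations (3 vs 3, dispersion 0.1)
gives a null p < 0.05 rate close to nominal, and planted log2FC = 1
effects are recovered to within ±0.15.  One known behavior: with strongly
one-sided DE (≳15% of genes shifted in one direction) trimmed-mean
normalization absorbs part of the shift, biasing estimated fold changes
toward zero by ~0.1 log2 units — this is shared with the reference TMM
implementation and is a property of composition normalization, not a bug.

The relaxed derepressed set (log2FC > 0.3, no FDR condition) deliberately
trades specificity for sensitivity because miRNA withdrawal shifts target
abundance only mildly; specificity is recovered downstream by the
PAR-CLIP intersection.  The relaxed set is subject only to the global cpm
filter.  A specificity screen reports the hypergeometric overlap of strict
DE sets between the family-specific sponge and a non-targeting sponge.

## Enrichment and intersection

Overrepresentation uses the exact hypergeometric upper tail P(X ≥ k).
For seed families the universe is the cpm-filtered gene set, K the
universe genes with a ≥2-replica family hit, n the relaxed derepressed
genes; BH is applied across families.  Gene-set overlap tables report
K, k, k/K, p and BH q per set; the universe defaults to the union of all
set members and the query because annotation universes are rarely
published, and it is explicit and configurable.  Sets disjoint from the
universe are flagged and excluded from the BH family.  The target list —
genes with log2FC above the relaxed cutoff and a ≥2-replica hit for a
family of interest — is sorted by descending log2FC with gene-id
tie-breaks, so repeated runs diff cleanly.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
with defaults: 500 single-exon genes (5'UTR 100–300 nt, CDS 300–900 nt,
3'UTR 200–2000 nt, uniform base composition, random strand, one contig
per gene), 50 true targets carrying 1–3 sites of one planted family
(miR-17 or miR-19 family; site types uniform over 8mer / 7mer-m8 /
7mer-A1, ≥ 60 nt apart), 3 PAR-CLIP replicas with 8–20 reads per site
(20–35 nt, sense strand, no indels), per-read crosslink conversion
probability 0.4, sequencing-error rate 0.002 per base, 0–5 background
reads per gene, and RNA-seq counts that are negative binomial
(variance = μ + 0.08 μ², baseline means log-normal with median 200) with
targets multiplied by 2^0.6 in the 3 target-sponge samples only; 3 control
and 3 non-targeting-sponge samples carry no effect.

Two generator guarantees make the truth table exact: a crosslinkable T is
placed within the 3 nt immediately 5' of every planted site (the first
existing T is used; one is written in if absent), so conversion evidence
falls inside the ±3 nt seed-proximity window by construction; and chance
occurrences of planted-family seed cores outside planted-site footprints
are rewritten (destroying a 6mer core destroys every longer site type
containing it), so non-target genes carry exactly zero planted-family
sites.  The first guarantee follows the generator's stated intent — the
crosslink must satisfy the downstream proximity filter — rather than a
wider 5 nt search that would silently fail it for ~18% of sites.

What the generator does **not** emulate: multi-exon UTRs (projection
across junctions is exercised by unit tests instead), alignment and
adapter artifacts, multimappers, quantitative CLIP signal differences
between conditions, batch effects, and library-composition extremes.
Passing end-to-end tests therefore demonstrates that the *procedures* are
implemented correctly and recover truth under the assumed data model, not
that the thresholds are optimal for any particular real dataset.

Everything is deterministic under `rng_seed`: each operation draws from a
`numpy` generator seeded by `[rng_seed, stream]` with a fixed stream id
per stage and replica, so stages can be re-run independently and full
reruns are byte-identical.

## Problem sizes and numerical notes

The default end-to-end run (500 genes, ~2.7k reads per replica) and the
calibration simulations (2000 genes) complete in seconds on one CPU; they
are the problem sizes used by the test suite and the acceptance script.
Kernel densities are evaluated exactly (no FFT approximation) on group
spans, which are short.  Hypergeometric tails come from
`scipy.stats.hypergeom.sf`; BH from `statsmodels` (`fdr_bh`), verified
against the hand step-up formula.  Degenerate inputs are defined: empty
mismatch sets give an all-zero mutation profile; groups without conversion
events yield no clusters; a single-gene TMM matrix warns and returns unit
factors; identical count columns give exactly zero log2FC.

## Known limitations

- The per-gene 3'UTR union discards isoform identity.
- The seed-family table is annotation data, not a derivation: the shipped
  miR-18 8mer string (AAGTGCAT) follows the published assignment and does
  not equal positions 1–8 of the canonical mature sequence; downstream
  site patterns are derived from motif7.  Users can supply their own table.
- The DE engine is a moderated t on log2-cpm, not an exact reproduction of
  edgeR/voom; published gene counts obtained with those tools will differ
  in detail.
- Cluster extension is a single pass; pathological read stacks could
  warrant iterative extension.
- Replicate cluster grouping is greedy; on the benign interval geometries
  tested it attains the exhaustive maximum number of disjoint groups, but
  this is not guaranteed in general.
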