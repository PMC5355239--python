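# spongeclip

Inference of a miRNA seed family's direct targetome by intersecting two
orthogonal genome-wide readouts:

1. **Physical binding** — AGO2 PAR-CLIP: clusters of short reads carrying
   T→C transitions (the footprint of 4-thiouridine crosslinking to the
   RISC complex), restricted to 3'UTRs and required to contain a miRNA
   seed match next to the crosslink site in at least two replicas.
2. **Functional derepression** — RNA-seq after expression of a miRNA
   *sponge* (a decoy transcript bearing tandem seed-complementary sites
   that sequesters an entire seed family): true targets increase in
   abundance when their miRNA is withdrawn.

Neither readout alone predicts regulation reliably — RISC association does
not imply abundance change, and expression response alone does not imply a
direct site.  Their intersection does both, and is the package's headline
output: the list of genes with log2FC > 0.3 under the family-specific
sponge **and** a replica-supported PAR-CLIP seed hit.

The package is a library first (`import spongeclip`), with narrative
scripts under `examples/` and a thin `spongeclip` CLI for file-based runs.
A synthetic-data generator with exact planted truth (seed sites, crosslink
positions, true fold changes) makes every stage testable without any
external data.

## The method in brief

**Cluster calling.** Overlapping reads are chained into groups
(≥ 5 reads).  Within a group, Gaussian kernel densities (bandwidth 3 nt)
are estimated for T→C conversion events and for covered but non-converted
T positions, each normalized to a probability density; clusters are maximal
runs where the conversion density exceeds the non-conversion density,
extended to read boundaries, subject to: length ≥ 10 nt, ≥ 5 reads, ≥ 1
conversion location.  The *mode location* (argmax of conversion density)
marks the crosslink.  All conversion logic is strand-aware (genomic A→G on
− reads is T→C in read orientation); reads shorter than 13 nt or carrying
any non-conversion mismatch are discarded.

**Seed matching.** Seed family motifs are stored 5'→3' (miRNA positions
2–8); target-site patterns are their reverse complements with the
canonical site types — 8mer, 7mer-m8, 7mer-A1, and 6mer (excluded
downstream).  A cluster survives filtering only if a non-6mer site of some
family intersects the window ±3 nt around its mode location; a gene is a
*hit* for a family when that occurs in ≥ 2 replicas.

**Differential expression.** Genes with cpm > 10 in more than two samples
are TMM-normalized and tested with a moderated t statistic on log2-cpm
(empirical-Bayes pooled variance).  Strict calls use |FC| > 1.5 at
BH-FDR < 0.1; the relaxed derepressed set uses log2FC > 0.3 with no FDR
condition, matching the mild effects miRNA withdrawal produces.

**Enrichment.** Seed-family overrepresentation among derepressed genes and
MSigDB-style gene-set overlaps (K, k, k/K) use the exact hypergeometric
upper tail with BH adjustment within each analysis.

## Worked example

```bash
python examples/05_full_targetome.py
```

runs the whole inference on the default synthetic conditions (500 genes,
50 true targets of the miR-17 and miR-19 seed families, 3 PAR-CLIP
replicas at 40% per-read conversion, 3 sponge vs. 3 control RNA-seq
libraries with a true derepression of 2^0.6 ≈ 1.5-fold) and prints, among
other things:

```
seed-family overrepresentation in derepressed genes:
    family_id   N  K   n  k    ratio            p            q
mir-17_family 500 22 105 15 0.681818 1.313345e-06 1.970018e-06
mir-18_family 500 16 105 11 0.687500 3.768170e-05 3.768170e-05
mir-19_family 500 29 105 27 0.931034 7.518785e-18 2.255635e-17

top target calls (gene, log2FC, families, replica support):
  G234  +1.27  mir-17_family  3 replicas  sites: 7mer-A1
  ...
recall 0.82 / precision 1.00 against the planted truth
```

Reading: of N = 500 expressed genes, K genes carry a ≥2-replica PAR-CLIP
hit for the family, n = 105 are derepressed (log2FC > 0.3), and k of those
overlap — a hypergeometric p far below 10⁻³ for the planted families.  The
final intersection recovers 41 of the 50 planted targets with no false
positives.

The other examples demonstrate individual capabilities: dataset generation
(`01`), cluster calling and region occupancy (`02`), seed-site typing
(`03`), and sponge DE with the specificity screen against a non-targeting
sponge (`04`).  The same stages are available from the shell:

```bash
spongeclip all --outdir run1 --seed 1
spongeclip callclusters --alignments run1/data/parclip_rep1.tsv \
    --annotation run1/data/transcripts.bed --fasta run1/data/genome.fa \
    --out-prefix rep1
```

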