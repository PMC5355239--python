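"""PAR-CLIP cluster calling from aligned reads with T→C conversion evidence.

The caller is a simplified reimplementation of the PARalyzer strategy:
reads are chained into overlap groups, a Gaussian kernel density is
estimated separately for T→C conversion events and for non-converted T
positions covered by reads, and clusters are the maximal runs where the
conversion density exceeds the non-conversion density, extended to read
boundaries.  Both densities are normalized by their event counts, so the
comparison is of *relative* signal concentration — conversion evidence that
is focally concentrated (a crosslink site) beats diffusely distributed
non-conversion background even when fewer than half of the reads carry the
transition.

All conversion logic is strand-aware and operates in read (transcript)
orientation: a genomic A→G mismatch on a − strand read counts as T→C.
Configuration field names mirror the conventional PARalyzer .ini keys.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .annotation import GenomicInterval, Region, RegionSet, SequenceStore

MUTATION_CLASSES = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

REGION_PRECEDENCE = ("3UTR", "CDS", "5UTR", "intron", "noncoding", "intergenic")


class ParclipError(ValueError):
    pass


@dataclass(frozen=True)
class Mismatch:
    """One aligned mismatch in genomic (forward-strand) terms."""

    pos: int
    ref: str
    read: str


@dataclass(frozen=True)
class AlignedRead:
    """A uniquely aligned read with its mismatch record.

    ``t_positions`` holds the genomic positions covered by the read whose
    *sense-strand* base is T (reference T on + reads, reference A on −
    reads); it feeds the non-conversion density.  It may be ``None`` when
    the reference sequence was unavailable at ingest, in which case the
    caller falls back to conversion locations observed in the read group.
    """

    chrom: str
    strand: str
    start: int
    read_len: int
    mismatches: tuple[Mismatch, ...] = ()
    t_positions: tuple[int, ...] | None = None

    @property
    def end(self) -> int:
        return self.start + self.read_len

    def __post_init__(self) -> None:
        for mm in self.mismatches:
            if not (self.start <= mm.pos < self.end):
                raise ParclipError(
                    f"mismatch at {mm.pos} outside read [{self.start},{self.end})"
                )


def is_conversion(strand: str, mm: Mismatch) -> bool:
    """True if the mismatch is a T→C transition in read orientation."""
    if strand == "+":
        return mm.ref == "T" and mm.read == "C"
    return mm.ref == "A" and mm.read == "G"


def mutation_class(strand: str, mm: Mismatch) -> str:
    """Mutation class (ref>read) in read orientation."""
    if strand == "+":
        return f"{mm.ref}>{mm.read}"
    return f"{_COMP[mm.ref]}>{_COMP[mm.read]}"


@dataclass(frozen=True)
class ParclipConfig:
    """Cluster-calling parameters (PARalyzer-style .ini values)."""

    bandwidth: float = 3.0
    conversion: str = "T>C"
    min_read_count_per_group: int = 5
    min_read_count_per_cluster: int = 5
    min_read_count_for_kde: int = 5
    min_cluster_size: int = 10
    min_conversion_locations: int = 1
    min_conversion_count: int = 1
    min_read_count_for_cluster_inclusion: int = 5
    min_read_length: int = 13
    max_non_conversion_mismatches: int = 0
    extend_by_read: bool = True
    max_seed_match_length: int = 8

    _INI_KEYS = {
        "BANDWIDTH": "bandwidth",
        "CONVERSION": "conversion",
        "MINIMUM_READ_COUNT_PER_GROUP": "min_read_count_per_group",
        "MINIMUM_READ_COUNT_PER_CLUSTER": "min_read_count_per_cluster",
        "MINIMUM_READ_COUNT_FOR_KDE": "min_read_count_for_kde",
        "MINIMUM_CLUSTER_SIZE": "min_cluster_size",
        "MINIMUM_CONVERSION_LOCATIONS_FOR_CLUSTER": "min_conversion_locations",
        "MINIMUM_CONVERSION_COUNT_FOR_CLUSTER": "min_conversion_count",
        "MINIMUM_READ_COUNT_FOR_CLUSTER_INCLUSION": "min_read_count_for_cluster_inclusion",
        "MINIMUM_READ_LENGTH": "min_read_length",
        "MAXIMUM_NUMBER_OF_NON_CONVERSION_MISMATCHES": "max_non_conversion_mismatches",
        "EXTEND_BY_READ": "extend_by_read",
        "MAXIMUM_SEED_MATCH_LENGTH": "max_seed_match_length",
    }

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ParclipError("bandwidth must be > 0")
        for name in (
            "min_read_count_per_group",
            "min_read_count_per_cluster",
            "min_read_count_for_kde",
            "min_cluster_size",
            "min_conversion_locations",
            "min_conversion_count",
            "min_read_count_for_cluster_inclusion",
            "min_read_length",
        ):
            if getattr(self, name) <= 0:
                raise ParclipError(f"{name} must be positive")
        if self.conversion != "T>C":
            raise ParclipError("only the T>C conversion chemistry is supported")

    @classmethod
    def from_ini(cls, path: str | os.PathLike) -> "ParclipConfig":
        """Read a key=value config whose keys mirror the PARalyzer .ini names."""
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" in line:
                    key, value = (x.strip() for x in line.split("=", 1))
                else:
                    key, value = line, "true"
                if key not in cls._INI_KEYS:
                    raise ParclipError(
                        f"{path}: line {lineno}: unknown key {key!r}; valid keys: "
                        + ", ".join(sorted(cls._INI_KEYS))
                    )
                attr = cls._INI_KEYS[key]
                if attr == "conversion":
                    kwargs[attr] = value
                elif attr == "extend_by_read":
                    kwargs[attr] = value.lower() in ("1", "true", "yes")
                elif attr == "bandwidth":
                    kwargs[attr] = float(value)
                else:
                    kwargs[attr] = int(value)
        return cls(**kwargs)

    def to_ini(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            for key, attr in self._INI_KEYS.items():
                fh.write(f"{key}={getattr(self, attr)}\n")


@dataclass
class ReadGroup:
    """Maximal set of reads chained by pairwise overlap on one strand."""

    chrom: str
    strand: str
    start: int
    end: int
    reads: list[AlignedRead]

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Cluster:
    """A called PAR-CLIP cluster with conversion evidence and mode location."""

    chrom: str
    strand: str
    start: int
    end: int
    read_count: int
    conversion_count: int
    conversion_locations: tuple[int, ...]
    mode_location: int
    replica: str | None = None
    gene_id: str | None = None
    region_label: str | None = None

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def with_annotation(self, gene_id: str | None, region_label: str) -> "Cluster":
        return replace(self, gene_id=gene_id, region_label=region_label)


# ---------------------------------------------------------------------------
# Ingest


def read_alignments_tsv(
    path: str | os.PathLike, reference: SequenceStore | None = None
) -> list[AlignedRead]:
    """Read the 7-column alignment TSV.

    Columns: chrom, strand, start, length, mm_pos, mm_ref, mm_read; the
    mismatch columns are comma-separated lists ('.' when the read has none).
    Bases are genomic forward-strand.  When a reference store is given,
    per-read sense-strand T positions are computed for the non-conversion
    density; otherwise they are left unset.
    """
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParclipError(
                    f"{path}: line {lineno}: expected 7 columns, got {len(fields)}"
                )
            chrom, strand, start_s, len_s, mmp, mmr, mmq = fields
            start, rlen = int(start_s), int(len_s)
            mms: tuple[Mismatch, ...] = ()
            if mmp != ".":
                positions = [int(x) for x in mmp.split(",")]
                refs = mmr.split(",")
                alts = mmq.split(",")
                if not (len(positions) == len(refs) == len(alts)):
                    raise ParclipError(
                        f"{path}: line {lineno}: mismatch columns disagree in length"
                    )
                mms = tuple(
                    Mismatch(p, r.upper(), a.upper())
                    for p, r, a in zip(positions, refs, alts)
                )
            t_pos = None
            if reference is not None:
                t_pos = _t_positions_from_ref(reference, chrom, strand, start, rlen)
            reads.append(AlignedRead(chrom, strand, start, rlen, mms, t_pos))
    return reads


def _t_positions_from_ref(
    reference: SequenceStore, chrom: str, strand: str, start: int, rlen: int
) -> tuple[int, ...]:
    seq = reference.fetch(chrom, start, start + rlen)
    base = "T" if strand == "+" else "A"
    return tuple(start + i for i, b in enumerate(seq) if b == base)


def write_alignments_tsv(reads: Iterable[AlignedRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            if r.mismatches:
                mmp = ",".join(str(m.pos) for m in r.mismatches)
                mmr = ",".join(m.ref for m in r.mismatches)
                mmq = ",".join(m.read for m in r.mismatches)
            else:
                mmp = mmr = mmq = "."
            fh.write(
                f"{r.chrom}\t{r.strand}\t{r.start}\t{r.read_len}\t{mmp}\t{mmr}\t{mmq}\n"
            )


def read_alignments_sam(path: str | os.PathLike) -> list[AlignedRead]:
    """Read unique-mapper records from SAM/BAM, recovering mismatches from MD.

    Insertions/deletions are not supported (PAR-CLIP reads are short and the
    upstream aligner is run without indels); records lacking an MD tag raise
    with advice to use the TSV ingest path.
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if not rec.has_tag("MD"):
                raise ParclipError(
                    f"record {rec.query_name}: no MD tag; mismatches are not "
                    "recoverable — realign with MD tags or use the alignment-TSV input"
                )
            strand = "-" if rec.is_reverse else "+"
            pairs = rec.get_aligned_pairs(with_seq=True)
            if any(q is None or r is None for q, r, _ in pairs):
                raise ParclipError(
                    f"record {rec.query_name}: indel alignments are not supported"
                )
            qseq = rec.query_sequence.upper()
            mms = []
            t_pos = []
            sense_t = "T" if strand == "+" else "A"
            for qpos, rpos, refbase in pairs:
                rb = refbase.upper()
                if rb == sense_t:
                    t_pos.append(rpos)
                if refbase.islower():
                    mms.append(Mismatch(rpos, rb, qseq[qpos]))
            reads.append(
                AlignedRead(
                    rec.reference_name,
                    strand,
                    rec.reference_start,
                    rec.reference_end - rec.reference_start,
                    tuple(mms),
                    tuple(t_pos),
                )
            )
    return reads


def apply_read_filters(
    reads: Iterable[AlignedRead], cfg: ParclipConfig
) -> list[AlignedRead]:
    """Drop short reads and reads with too many non-conversion mismatches."""
    kept = []
    for r in reads:
        if r.read_len < cfg.min_read_length:
            continue
        non_conv = sum(1 for mm in r.mismatches if not is_conversion(r.strand, mm))
        if non_conv > cfg.max_non_conversion_mismatches:
            continue
        kept.append(r)
    return kept


def ingest_alignments(
    path: str | os.PathLike,
    cfg: ParclipConfig,
    reference: SequenceStore | None = None,
) -> list[AlignedRead]:
    """Read alignments (SAM/BAM or TSV by extension) and apply read filters."""
    p = os.fspath(path)
    if p.endswith((".sam", ".bam")):
        raw = read_alignments_sam(p)
    else:
        raw = read_alignments_tsv(p, reference)
    return apply_read_filters(raw, cfg)


# ---------------------------------------------------------------------------
# Mutation profile


def mutation_profile(reads: Iterable[AlignedRead]) -> dict[str, float]:
    """Percentage of each of the 12 mutation classes, in read orientation.

    Returns an all-zero profile (every class 0.0) when no mismatch exists;
    callers can detect that state via ``sum(profile.values()) == 0``.
    """
    counts = {c: 0 for c in MUTATION_CLASSES}
    total = 0
    for r in reads:
        for mm in r.mismatches:
            counts[mutation_class(r.strand, mm)] += 1
            total += 1
    if total == 0:
        return {c: 0.0 for c in MUTATION_CLASSES}
    return {c: 100.0 * n / total for c, n in counts.items()}


# ---------------------------------------------------------------------------
# Grouping and KDE


def group_reads(reads: Sequence[AlignedRead], cfg: ParclipConfig) -> list[ReadGroup]:
    """Chain overlapping reads into maximal groups per (chrom, strand).

    Groups with fewer than ``min_read_count_per_group`` reads are discarded.
    """
    ordered = sorted(reads, key=lambda r: (r.chrom, r.strand, r.start, r.end))
    groups: list[ReadGroup] = []
    cur: list[AlignedRead] = []
    cur_end = -1
    for r in ordered:
        if cur and (
            r.chrom != cur[0].chrom or r.strand != cur[0].strand or r.start >= cur_end
        ):
            if len(cur) >= cfg.min_read_count_per_group:
                groups.append(
                    ReadGroup(cur[0].chrom, cur[0].strand, cur[0].start, cur_end, cur)
                )
            cur, cur_end = [], -1
        cur.append(r)
        cur_end = max(cur_end, r.end)
    if cur and len(cur) >= cfg.min_read_count_per_group:
        groups.append(ReadGroup(cur[0].chrom, cur[0].strand, cur[0].start, cur_end, cur))
    return groups


def _group_events(group: ReadGroup) -> tuple[list[int], list[int]]:
    """Conversion events and non-conversion events (positions, with multiplicity)."""
    conv: list[int] = []
    per_read_conv: list[set[int]] = []
    for r in group.reads:
        cpos = {mm.pos for mm in r.mismatches if is_conversion(r.strand, mm)}
        per_read_conv.append(cpos)
        conv.extend(sorted(cpos))
    # T universe: per-read reference T positions if known, otherwise the
    # conversion locations observed anywhere in the group.
    fallback = sorted({p for cs in per_read_conv for p in cs})
    nonconv: list[int] = []
    for r, cpos in zip(group.reads, per_read_conv):
        ts = (
            r.t_positions
            if r.t_positions is not None
            else [p for p in fallback if r.start <= p < r.end]
        )
        nonconv.extend(p for p in ts if r.start <= p < r.end and p not in cpos)
    return conv, nonconv


def _kernel_density(positions: np.ndarray, events: Sequence[int], bandwidth: float) -> np.ndarray:
    """Gaussian mixture density over integer positions (normalized by count)."""
    if len(events) == 0:
        return np.zeros(len(positions))
    ev = np.asarray(events, dtype=float)
    z = (positions[:, None] - ev[None, :]) / bandwidth
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (
        bandwidth * math.sqrt(2.0 * math.pi) * len(ev)
    )
    return dens


def kde_signal(
    group: ReadGroup, cfg: ParclipConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-position (positions, conversion_density, nonconversion_density).

    Each density is the Gaussian kernel mixture over its event set with the
    configured bandwidth, normalized by the event count so the two signals
    compare the relative concentration of conversion vs non-conversion
    evidence.  A group without conversion (or T) events yields a zero
    signal and no clusters downstream.
    """
    positions = np.arange(group.start, group.end)
    conv, nonconv = _group_events(group)
    return (
        positions,
        _kernel_density(positions, conv, cfg.bandwidth),
        _kernel_density(positions, nonconv, cfg.bandwidth),
    )


# ---------------------------------------------------------------------------
# Cluster calling


def call_clusters(group: ReadGroup, cfg: ParclipConfig) -> list[Cluster]:
    """Call clusters in one read group.

    Candidate intervals are maximal runs where the conversion density
    strictly exceeds the non-conversion density; with ``extend_by_read``
    each run is widened to the outermost boundaries of the reads that
    overlap it.  Clusters failing the size / read-count / conversion
    thresholds are discarded.  The mode location is the position of maximal
    conversion density within the cluster span (leftmost on ties).
    """
    if len(group.reads) < cfg.min_read_count_for_kde:
        return []
    positions, conv_d, nonconv_d = kde_signal(group, cfg)
    mask = (conv_d > nonconv_d) & (conv_d > 0)
    if not mask.any():
        return []

    conv_events, _ = _group_events(group)
    conv_by_pos: dict[int, int] = {}
    for p in conv_events:
        conv_by_pos[p] = conv_by_pos.get(p, 0) + 1

    clusters = []
    seen_spans: set[tuple[int, int]] = set()
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for run_start, run_stop in zip(idx[::2], idx[1::2]):
        lo = int(positions[run_start])
        hi = int(positions[run_stop - 1]) + 1
        span_reads = [r for r in group.reads if r.start < hi and r.end > lo]
        if cfg.extend_by_read and span_reads:
            lo = min(lo, min(r.start for r in span_reads))
            hi = max(hi, max(r.end for r in span_reads))
            span_reads = [r for r in group.reads if r.start < hi and r.end > lo]
        if (lo, hi) in seen_spans:  # two runs can extend to one read footprint
            continue
        seen_spans.add((lo, hi))
        if hi - lo < cfg.min_cluster_size:
            continue
        read_count = len(span_reads)
        if read_count < max(
            cfg.min_read_count_per_cluster, cfg.min_read_count_for_cluster_inclusion
        ):
            continue
        locs = tuple(sorted(p for p in conv_by_pos if lo <= p < hi))
        count = sum(conv_by_pos[p] for p in locs)
        if len(locs) < cfg.min_conversion_locations or count < cfg.min_conversion_count:
            continue
        sel = (positions >= lo) & (positions < hi)
        mode = int(positions[sel][int(np.argmax(conv_d[sel]))])
        clusters.append(
            Cluster(
                chrom=group.chrom,
                strand=group.strand,
                start=lo,
                end=hi,
                read_count=read_count,
                conversion_count=count,
                conversion_locations=locs,
                mode_location=mode,
            )
        )
    return clusters


def call_all_clusters(
    reads: Sequence[AlignedRead], cfg: ParclipConfig, replica: str | None = None
) -> list[Cluster]:
    """Group reads genome-wide and call clusters in every group."""
    clusters = []
    for group in group_reads(reads, cfg):
        for c in call_clusters(group, cfg):
            clusters.append(replace(c, replica=replica))
    return clusters


# ---------------------------------------------------------------------------
# Annotation / occupancy


def annotate_clusters(
    clusters: Sequence[Cluster], regions: RegionSet
) -> tuple[list[Cluster], dict[str, float]]:
    """Assign each cluster a gene and region label by maximal overlap.

    Ties are broken by the fixed precedence 3UTR > CDS > 5UTR > intron;
    clusters overlapping no same-strand region are labeled "intergenic".
    Returns the annotated clusters and the percent occupancy per region
    class (percentages sum to 100 when any cluster exists).
    """
    from intervaltree import IntervalTree

    trees: dict[tuple[str, str], IntervalTree] = {}
    for r in regions:
        trees.setdefault((r.chrom, r.strand), IntervalTree()).addi(r.start, r.end, r)

    rank = {label: i for i, label in enumerate(REGION_PRECEDENCE)}
    annotated = []
    occupancy: dict[str, int] = {}
    for c in clusters:
        tree = trees.get((c.chrom, c.strand))
        best_label, best_gene = "intergenic", None
        if tree is not None:
            by_label: dict[str, int] = {}
            gene_overlap: dict[tuple[str, str], int] = {}
            for hit in tree.overlap(c.start, c.end):
                reg: Region = hit.data
                ov = min(c.end, reg.end) - max(c.start, reg.start)
                by_label[reg.label] = by_label.get(reg.label, 0) + ov
                key = (reg.label, reg.gene_id)
                gene_overlap[key] = gene_overlap.get(key, 0) + ov
            if by_label:
                best_label = min(
                    by_label, key=lambda lab: (-by_label[lab], rank.get(lab, 99))
                )
                candidates = {
                    g: ov for (lab, g), ov in gene_overlap.items() if lab == best_label
                }
                best_gene = min(candidates, key=lambda g: (-candidates[g], g))
        annotated.append(c.with_annotation(best_gene, best_label))
        occupancy[best_label] = occupancy.get(best_label, 0) + 1
    total = sum(occupancy.values())
    occupancy_pct = {
        lab: 100.0 * n / total for lab, n in occupancy.items()
    } if total else {}
    return annotated, occupancy_pct


# ---------------------------------------------------------------------------
# Cluster I/O (BED6+4: read_count, conversion_count, conversion_locations, mode)


def write_clusters_bed(clusters: Iterable[Cluster], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in sorted(clusters, key=lambda c: (c.chrom, c.start, c.end)):
            name = f"{c.gene_id or '.'}|{c.region_label or '.'}"
            locs = ",".join(str(p) for p in c.conversion_locations)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t0\t{c.strand}\t"
                f"{c.read_count}\t{c.conversion_count}\t{locs}\t{c.mode_location}\n"
            )


def read_clusters_bed(path: str | os.PathLike, replica: str | None = None) -> list[Cluster]:
    clusters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 10:
                raise ParclipError(
                    f"{path}: line {lineno}: expected 10 columns (BED6+4)"
                )
            gene, label = f[3].split("|", 1)
            clusters.append(
                Cluster(
                    chrom=f[0],
                    strand=f[5],
                    start=int(f[1]),
                    end=int(f[2]),
                    read_count=int(f[6]),
                    conversion_count=int(f[7]),
                    conversion_locations=tuple(
                        int(x) for x in f[8].split(",") if x
                    ),
                    mode_location=int(f[9]),
                    replica=replica,
                    gene_id=None if gene == "." else gene,
                    region_label=None if label == "." else label,
                )
            )
    return clusters
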