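"""Transcript annotation, derived gene regions and sequence access.

All coordinates inside the package are 0-based half-open on the genomic
forward strand (BED convention).  GTF input (1-based inclusive) is converted
on read.  Gene structures are decomposed into labeled regions
(5UTR / CDS / 3UTR / intron); the 3'UTR union across a gene's transcripts is
the coordinate frame used for cluster assignment and seed-site projection.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pyfaidx

REGION_LABELS = ("5UTR", "CDS", "3UTR", "intron")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised on malformed annotation input or invariant violations."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"interval start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons plus an optional CDS interval.

    ``cds_start``/``cds_end`` are genomic coordinates (not transcript
    offsets); they are ``None`` for non-coding transcripts.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for start, end in self.exons:
            if start >= end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end
        if (self.cds_start is None) != (self.cds_end is None):
            raise AnnotationError(
                f"transcript {self.transcript_id}: cds_start/cds_end must both be set or absent"
            )
        if self.cds_start is not None:
            if self.cds_start >= self.cds_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty CDS"
                )
            if not self._position_in_exons(self.cds_start) or not self._position_in_exons(
                self.cds_end - 1
            ):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS boundaries outside exons"
                )

    def _position_in_exons(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class Region:
    """A labeled piece of a transcript (5UTR / CDS / 3UTR / intron / other)."""

    gene_id: str
    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str
    label: str

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class RegionSet:
    """Collection of labeled regions for a set of transcripts."""

    regions: list[Region] = field(default_factory=list)

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def by_label(self, label: str) -> list[Region]:
        return [r for r in self.regions if r.label == label]

    def utr3_by_gene(self) -> dict[str, list[GenomicInterval]]:
        """Union of 3'UTR intervals per gene, merged, sorted by start.

        The union across a gene's transcript isoforms is the gene-level
        3'UTR frame used downstream for cluster assignment.
        """
        raw: dict[str, list[GenomicInterval]] = {}
        for r in self.by_label("3UTR"):
            raw.setdefault(r.gene_id, []).append(r.interval)
        merged: dict[str, list[GenomicInterval]] = {}
        for gene, ivs in raw.items():
            ivs = sorted(ivs, key=lambda iv: (iv.chrom, iv.start))
            out: list[GenomicInterval] = []
            for iv in ivs:
                if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end:
                    last = out.pop()
                    out.append(
                        GenomicInterval(
                            last.chrom, last.start, max(last.end, iv.end), last.strand
                        )
                    )
                else:
                    out.append(iv)
            merged[gene] = out
        return merged

    def to_bed(self, path: str | os.PathLike) -> None:
        """Write regions as BED6 (name = gene|transcript|label, score = 0)."""
        with open(path, "w") as fh:
            for r in sorted(
                self.regions, key=lambda r: (r.chrom, r.start, r.end, r.label)
            ):
                name = f"{r.gene_id}|{r.transcript_id}|{r.label}"
                fh.write(
                    f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n"
                )

    @classmethod
    def from_bed(cls, path: str | os.PathLike) -> "RegionSet":
        regions = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise AnnotationError(
                        f"{path}: line {lineno}: expected >=6 BED fields, got {len(fields)}"
                    )
                chrom, start, end, name, _score, strand = fields[:6]
                try:
                    gene_id, transcript_id, label = name.split("|", 2)
                except ValueError as exc:
                    raise AnnotationError(
                        f"{path}: line {lineno}: name is not gene|transcript|label"
                    ) from exc
                regions.append(
                    Region(gene_id, transcript_id, chrom, int(start), int(end), strand, label)
                )
        return cls(regions)


# ---------------------------------------------------------------------------
# Region derivation


def derive_regions(
    t: TranscriptModel, noncoding_label: str = "noncoding"
) -> RegionSet:
    """Decompose a transcript into labeled 5UTR / CDS / 3UTR / intron regions.

    On the + strand exonic sequence upstream of the CDS is 5UTR and
    downstream is 3UTR; the − strand mirrors this.  Introns (gaps between
    exons) are labeled regardless of coding status.  Non-coding transcripts
    get their whole exonic span labeled ``noncoding_label`` and are thereby
    excluded from 3'UTR-restricted analyses by default.
    """
    regions: list[Region] = []

    def add(start: int, end: int, label: str) -> None:
        if start < end:
            regions.append(
                Region(t.gene_id, t.transcript_id, t.chrom, start, end, t.strand, label)
            )

    for (s1, e1), (s2, _e2) in zip(t.exons, t.exons[1:]):
        add(e1, s2, "intron")

    if not t.is_coding:
        for s, e in t.exons:
            add(s, e, noncoding_label)
        return RegionSet(sorted(regions, key=lambda r: r.start))

    left_label = "5UTR" if t.strand == "+" else "3UTR"
    right_label = "3UTR" if t.strand == "+" else "5UTR"
    for s, e in t.exons:
        add(max(s, 0), min(e, t.cds_start), left_label)
        add(max(s, t.cds_start), min(e, t.cds_end), "CDS")
        add(max(s, t.cds_end), e, right_label)
    return RegionSet(sorted(regions, key=lambda r: (r.start, r.label)))


def derive_all_regions(
    transcripts: Iterable[TranscriptModel], noncoding_label: str = "noncoding"
) -> RegionSet:
    out = RegionSet()
    for t in transcripts:
        out.regions.extend(derive_regions(t, noncoding_label).regions)
    return out


# ---------------------------------------------------------------------------
# Annotation readers


def load_transcripts(path: str | os.PathLike) -> list[TranscriptModel]:
    """Load transcript models from a GTF (ensembl dialect) or BED12 file.

    The format is chosen by file extension (.gtf/.gff → GTF, otherwise
    BED12).  Coordinates are normalized to 0-based half-open.
    """
    path = os.fspath(path)
    if path.endswith((".gtf", ".gff", ".gtf.gz")):
        return _load_gtf(path)
    return _load_bed12(path)


def _load_gtf(path: str) -> list[TranscriptModel]:
    import gffutils

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) < 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated GTF fields"
                )

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: feature at {feat.seqid}:{feat.start} lacks "
                f"gene_id/transcript_id attributes"
            ) from exc
        rec = exons.setdefault(
            tid, {"gene": gid, "chrom": feat.seqid, "strand": feat.strand, "exons": [], "cds": []}
        )
        # GTF is 1-based inclusive; convert to 0-based half-open.
        iv = (feat.start - 1, feat.end)
        if feat.featuretype == "exon":
            rec["exons"].append(iv)
        else:
            rec["cds"].append(iv)

    models = []
    for tid, rec in exons.items():
        exs = tuple(sorted(rec["exons"]))
        cds_start = cds_end = None
        if rec["cds"]:
            cds_start = min(s for s, _ in rec["cds"])
            cds_end = max(e for _, e in rec["cds"])
        models.append(
            TranscriptModel(
                gene_id=rec["gene"],
                transcript_id=tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=exs,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return sorted(models, key=lambda m: (m.chrom, m.span, m.transcript_id))


def _load_bed12(path: str) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 12 BED fields, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start = int(fields[1])
                name = fields[3]
                strand = fields[5]
                thick_start = int(fields[6])
                thick_end = int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: malformed BED12 numeric field: {exc}"
                ) from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise AnnotationError(
                    f"{path}: line {lineno}: blockCount disagrees with block lists"
                )
            exs = tuple((start + bs, start + bs + sz) for bs, sz in zip(starts, sizes))
            # gene id convention: "gene|transcript" in the name field, else
            # the name serves as both.
            if "|" in name:
                gene_id, transcript_id = name.split("|", 1)
            else:
                gene_id = transcript_id = name
            cds_start = cds_end = None
            if thick_end > thick_start:
                cds_start, cds_end = thick_start, thick_end
            models.append(
                TranscriptModel(
                    gene_id=gene_id,
                    transcript_id=transcript_id,
                    chrom=chrom,
                    strand=strand,
                    exons=exs,
                    cds_start=cds_start,
                    cds_end=cds_end,
                )
            )
    return models


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            start, end = t.span
            name = (
                t.gene_id
                if t.gene_id == t.transcript_id
                else f"{t.gene_id}|{t.transcript_id}"
            )
            thick_start = t.cds_start if t.is_coding else start
            thick_end = t.cds_end if t.is_coding else start
            sizes = ",".join(str(e - s) for s, e in t.exons)
            offsets = ",".join(str(s - start) for s, _ in t.exons)
            fh.write(
                f"{t.chrom}\t{start}\t{end}\t{name}\t0\t{t.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(t.exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Sequences


class SequenceStore:
    """Sequence access keyed by chromosome/contig identifier.

    Wraps either an in-memory mapping of name → sequence or an indexed
    FASTA file (via pyfaidx).  ``fetch`` returns forward-strand sequence.
    """

    def __init__(self, source: Mapping[str, str] | pyfaidx.Fasta):
        self._source = source

    def __contains__(self, chrom: str) -> bool:
        try:
            self[chrom]
        except KeyError:
            return False
        return True

    def __getitem__(self, chrom: str) -> str:
        try:
            seq = self._source[chrom]
        except KeyError as exc:
            raise KeyError(f"sequence {chrom!r} not found in store") from exc
        return str(seq).upper()

    def fetch(self, chrom: str, start: int, end: int) -> str:
        return self[chrom][start:end]


def load_fasta(path: str | os.PathLike) -> SequenceStore:
    """Open an (indexed) FASTA file as a SequenceStore."""
    return SequenceStore(pyfaidx.Fasta(os.fspath(path)))


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def utr3_sequence(
    gene_id: str, store: SequenceStore, regions: RegionSet
) -> str:
    """3'UTR sequence of a gene, 5'→3' in transcript orientation.

    Minus-strand intervals are reverse-complemented and ordered so the
    returned string reads in the direction of translation read-through.
    An annotated gene without a 3'UTR yields the empty string.
    """
    utr = regions.utr3_by_gene().get(gene_id, [])
    if not utr:
        return ""
    strand = utr[0].strand
    for iv in utr:
        if iv.chrom not in store:
            raise KeyError(f"sequence {iv.chrom!r} not found for gene {gene_id}")
    if strand == "+":
        return "".join(store.fetch(iv.chrom, iv.start, iv.end) for iv in utr)
    return "".join(
        revcomp(store.fetch(iv.chrom, iv.start, iv.end)) for iv in reversed(utr)
    )


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass
class GeneSetCollection:
    """Named gene sets: set name → (description, members)."""

    sets: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]

    def description(self, name: str) -> str:
        return self.sets[name][0]

    def K(self, name: str) -> int:
        return len(self.sets[name][1])


def load_gmt(path: str | os.PathLike) -> GeneSetCollection:
    """Read an MSigDB-style GMT file (name, description, members...)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(
                    f"{path}: line {lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                raise AnnotationError(f"{path}: line {lineno}: gene set {name} is empty")
            coll.sets[name] = (desc, members)
    return coll


def write_gmt(coll: GeneSetCollection, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in coll.sets.items():
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")
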