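"""Synthetic PAR-CLIP + sponge-RNA-seq datasets with known planted truth.

The generator emulates the statistical structure the pipeline assumes: each
gene is a single-exon transcript (5'UTR / CDS / 3'UTR) on its own contig;
a chosen subset of genes ("true targets") carries seed sites of the planted
miRNA families in the 3'UTR with a crosslinkable T immediately 5' of each
site; PAR-CLIP replicas place short sense-strand reads over the planted
sites with a per-read T→C conversion probability at the crosslink plus a
uniform sequencing-error background; and RNA-seq counts are negative
binomial with targets derepressed (multiplied by 2^log2fc) only under the
family-specific sponge.  Chance occurrences of planted-family seed patterns
outside planted sites are rewritten so the truth table is exact.

Everything is deterministic under a fixed ``rng_seed``; each operation uses
a seed stream derived from it, so stages can be re-run independently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import (
    RegionSet,
    SequenceStore,
    TranscriptModel,
    derive_all_regions,
    revcomp,
    write_bed12,
    write_fasta,
)
from .parclip import AlignedRead, Mismatch, write_alignments_tsv
from .seeds import SeedFamily, default_families, site_pattern

BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    rng_seed: int = 1
    n_genes: int = 500
    utr3_len_range: tuple[int, int] = (200, 2000)
    utr5_len_range: tuple[int, int] = (100, 300)
    cds_len_range: tuple[int, int] = (300, 900)
    n_true_targets: int = 50
    planted_families: tuple[str, ...] = ("mir-17_family", "mir-19_family")
    sites_per_target: tuple[int, int] = (1, 3)
    site_conversion_rate: float = 0.4
    background_error_rate: float = 0.002
    reads_per_true_site: tuple[int, int] = (8, 20)
    read_len_range: tuple[int, int] = (20, 35)
    background_reads_per_gene: tuple[int, int] = (0, 5)
    parclip_replicas: int = 3
    n_sponge_samples: int = 3
    n_control_samples: int = 3
    n_other_samples: int = 3
    target_log2fc: float = 0.6
    nb_dispersion: float = 0.08
    baseline_median: float = 200.0
    baseline_log_sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.site_conversion_rate <= 1):
            raise SimulationError("site_conversion_rate must be in [0, 1]")
        if not (0 <= self.background_error_rate <= 1):
            raise SimulationError("background_error_rate must be in [0, 1]")
        if self.n_true_targets > self.n_genes:
            raise SimulationError("n_true_targets cannot exceed n_genes")
        for name in ("n_genes", "parclip_replicas", "n_sponge_samples", "n_control_samples"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream])


@dataclass(frozen=True)
class PlantedSite:
    family_id: str
    utr_offset: int
    site_type: str
    pattern: str
    crosslink_utr_offset: int


@dataclass
class TruthTable:
    """Ground truth: per gene, target status, planted sites and true log2fc."""

    records: dict[str, dict] = field(default_factory=dict)

    def is_target(self, gene: str) -> bool:
        return self.records.get(gene, {}).get("is_target", False)

    @property
    def target_genes(self) -> set[str]:
        return {g for g, r in self.records.items() if r["is_target"]}

    def sites(self, gene: str) -> tuple[PlantedSite, ...]:
        return self.records.get(gene, {}).get("sites", ())

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tis_target\ttrue_log2fc\tfamily_id\tutr_offset\t"
                "site_type\tpattern\tcrosslink_utr_offset\n"
            )
            for gene in sorted(self.records):
                rec = self.records[gene]
                if rec["sites"]:
                    for s in rec["sites"]:
                        fh.write(
                            f"{gene}\t{int(rec['is_target'])}\t{rec['true_log2fc']}\t"
                            f"{s.family_id}\t{s.utr_offset}\t{s.site_type}\t"
                            f"{s.pattern}\t{s.crosslink_utr_offset}\n"
                        )
                else:
                    fh.write(
                        f"{gene}\t{int(rec['is_target'])}\t{rec['true_log2fc']}\t"
                        ".\t.\t.\t.\t.\n"
                    )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "TruthTable":
        truth = cls()
        df = pd.read_csv(path, sep="\t", dtype=str)
        for gene, grp in df.groupby("gene_id", sort=True):
            first = grp.iloc[0]
            sites = tuple(
                PlantedSite(
                    r["family_id"],
                    int(r["utr_offset"]),
                    r["site_type"],
                    r["pattern"],
                    int(r["crosslink_utr_offset"]),
                )
                for _, r in grp.iterrows()
                if r["family_id"] != "."
            )
            truth.records[gene] = {
                "is_target": first["is_target"] == "1",
                "true_log2fc": float(first["true_log2fc"]),
                "sites": sites,
            }
        return truth


@dataclass
class SyntheticAnnotation:
    """Gene models plus mutable sense-strand transcript sequences."""

    transcripts: list[TranscriptModel]
    sense_seqs: dict[str, str]  # gene_id -> transcript-orientation sequence
    structure: dict[str, dict]  # gene_id -> {utr5, cds, utr3, strand, chrom}

    def genome(self) -> dict[str, str]:
        """Forward-strand contig sequences (one contig per gene)."""
        out = {}
        for t in self.transcripts:
            seq = self.sense_seqs[t.gene_id]
            out[t.chrom] = seq if t.strand == "+" else revcomp(seq)
        return out

    def sequence_store(self) -> SequenceStore:
        return SequenceStore(self.genome())

    def regions(self) -> RegionSet:
        return derive_all_regions(self.transcripts)

    def utr3_bounds(self, gene: str) -> tuple[int, int]:
        """Transcript-coordinate [start, end) of the 3'UTR."""
        st = self.structure[gene]
        t0 = st["utr5"] + st["cds"]
        return t0, t0 + st["utr3"]

    def tx_to_genomic(self, gene: str, t_pos: int) -> int:
        st = self.structure[gene]
        tx_len = st["utr5"] + st["cds"] + st["utr3"]
        return t_pos if st["strand"] == "+" else tx_len - 1 - t_pos


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def make_annotation(cfg: SimConfig) -> SyntheticAnnotation:
    """Generate single-transcript genes with 5'UTR/CDS/3'UTR and sequences."""
    rng = cfg.rng(0)
    transcripts = []
    sense_seqs = {}
    structure = {}
    width = len(str(cfg.n_genes))
    for i in range(cfg.n_genes):
        gene = f"G{i + 1:0{width}d}"
        u5 = int(rng.integers(cfg.utr5_len_range[0], cfg.utr5_len_range[1] + 1))
        cds = int(rng.integers(cfg.cds_len_range[0], cfg.cds_len_range[1] + 1))
        u3 = int(rng.integers(cfg.utr3_len_range[0], cfg.utr3_len_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        tx_len = u5 + cds + u3
        seq = _random_seq(rng, tx_len)
        chrom = f"chr_{gene}"
        if strand == "+":
            cds_start, cds_end = u5, u5 + cds
        else:
            cds_start, cds_end = u3, u3 + cds
        transcripts.append(
            TranscriptModel(
                gene_id=gene,
                transcript_id=f"{gene}.t1",
                chrom=chrom,
                strand=strand,
                exons=((0, tx_len),),
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
        sense_seqs[gene] = seq
        structure[gene] = {"utr5": u5, "cds": cds, "utr3": u3, "strand": strand, "chrom": chrom}
    return SyntheticAnnotation(transcripts, sense_seqs, structure)


def _scrub_patterns(
    utr: list[str],
    families: Sequence[SeedFamily],
    footprints: list[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    """Rewrite chance occurrences of planted-family seed cores in a UTR.

    Removing the 6mer core removes every longer site type containing it.
    Footprint bases (planted sites and their crosslink T) are never touched.
    """
    protected = set()
    for lo, hi in footprints:
        protected.update(range(lo, hi))
    cores = [site_pattern(f, "6mer") for f in families]
    for _ in range(100):
        seq = "".join(utr)
        offending = []
        for core in cores:
            start = seq.find(core)
            while start != -1:
                span = set(range(start, start + 6))
                if not (span & protected):
                    offending.append((start, start + 6))
                elif not span <= protected:
                    # straddles a footprint edge: mutate only outside it
                    if any(p not in protected for p in span):
                        offending.append((start, start + 6))
                start = seq.find(core, start + 1)
        if not offending:
            return
        for lo, hi in offending:
            free = [p for p in range(lo, hi) if p not in protected]
            if not free:
                continue
            p = free[len(free) // 2]
            utr[p] = str(rng.choice([b for b in BASES if b != utr[p]]))
    raise SimulationError("failed to scrub chance seed occurrences (pathological UTR)")


def plant_sites(cfg: SimConfig, ann: SyntheticAnnotation) -> TruthTable:
    """Plant seed sites in target-gene 3'UTRs and scrub chance occurrences.

    Each target receives 1–3 sites of one planted family, with the site type
    drawn from {7mer-m8, 7mer-A1, 8mer}.  A crosslinkable T is guaranteed in
    the 3 nt immediately 5' of every site (inserted when absent), so that
    conversion evidence concentrates within the seed-proximity window used
    by the cluster filter.  Non-target UTRs end up with zero planted-family
    matches.
    """
    rng = cfg.rng(1)
    fam_by_id = {f.family_id: f for f in default_families()}
    try:
        planted = [fam_by_id[fid] for fid in cfg.planted_families]
    except KeyError as exc:
        raise SimulationError(f"unknown planted family: {exc}") from exc

    genes = sorted(ann.sense_seqs)
    target_idx = rng.choice(len(genes), size=cfg.n_true_targets, replace=False)
    targets = {genes[i] for i in target_idx}

    truth = TruthTable()
    site_types = ("7mer-m8", "7mer-A1", "8mer")
    for gene in genes:
        st = ann.structure[gene]
        u3_start, u3_end = ann.utr3_bounds(gene)
        seq = list(ann.sense_seqs[gene])
        utr = seq[u3_start:u3_end]
        sites: list[PlantedSite] = []
        footprints: list[tuple[int, int]] = []
        if gene in targets:
            family = planted[int(rng.integers(0, len(planted)))]
            n_sites = int(
                rng.integers(cfg.sites_per_target[0], cfg.sites_per_target[1] + 1)
            )
            utr_len = len(utr)
            placed = 0
            attempts = 0
            while placed < n_sites and attempts < 200:
                attempts += 1
                stype = site_types[int(rng.integers(0, 3))]
                pattern = site_pattern(family, stype)
                offset = int(rng.integers(10, utr_len - len(pattern) - 5))
                # keep planted sites well separated so clusters are distinct
                if any(abs(offset - s.utr_offset) < 60 for s in sites):
                    continue
                for i, b in enumerate(pattern):
                    utr[offset + i] = b
                # crosslink: first T within 3 nt 5' of the site, else insert one
                crosslink = None
                for d in (1, 2, 3):
                    if utr[offset - d] == "T":
                        crosslink = offset - d
                        break
                if crosslink is None:
                    utr[offset - 1] = "T"
                    crosslink = offset - 1
                sites.append(PlantedSite(family.family_id, offset, stype, pattern, crosslink))
                footprints.append((min(crosslink, offset - 3), offset + len(pattern)))
                placed += 1
            if placed == 0:
                raise SimulationError(f"could not place any site in {gene} (UTR too short)")
        _scrub_patterns(utr, planted, footprints, rng)
        seq[u3_start:u3_end] = utr
        ann.sense_seqs[gene] = "".join(seq)
        truth.records[gene] = {
            "is_target": gene in targets,
            "true_log2fc": cfg.target_log2fc if gene in targets else 0.0,
            "sites": tuple(sites),
        }
    return truth


def simulate_parclip(
    cfg: SimConfig,
    ann: SyntheticAnnotation,
    truth: TruthTable,
    replica_index: int,
) -> list[AlignedRead]:
    """One PAR-CLIP replica: site-covering reads plus scattered background.

    Reads are sense-strand, 20–35 nt, indel-free.  Every read covering a
    planted crosslink converts its T with ``site_conversion_rate``; every
    other covered position mutates with ``background_error_rate``.
    Replica streams are independent but reproducible from the seed.
    """
    rng = cfg.rng(100 + replica_index)
    reads: list[AlignedRead] = []
    lo_r, hi_r = cfg.reads_per_true_site
    lo_l, hi_l = cfg.read_len_range
    for gene in sorted(ann.sense_seqs):
        st = ann.structure[gene]
        seq = ann.sense_seqs[gene]
        tx_len = len(seq)
        u3_start, _ = ann.utr3_bounds(gene)
        site_jobs = []
        for site in truth.sites(gene):
            n = int(rng.integers(lo_r, hi_r + 1))
            crosslink_t = u3_start + site.crosslink_utr_offset
            site_end_t = u3_start + site.utr_offset + len(site.pattern)
            site_jobs.append((n, crosslink_t, site_end_t))
        for n, crosslink_t, site_end_t in site_jobs:
            for _ in range(n):
                length = int(rng.integers(lo_l, hi_l + 1))
                lo_start = max(0, site_end_t - length)
                hi_start = min(crosslink_t, tx_len - length)
                start = int(rng.integers(lo_start, hi_start + 1))
                converted = rng.random() < cfg.site_conversion_rate
                reads.append(
                    _make_read(
                        ann, gene, seq, start, length, rng,
                        cfg.background_error_rate,
                        crosslink=crosslink_t if converted else None,
                        skip={crosslink_t},
                    )
                )
        n_bg = int(
            rng.integers(cfg.background_reads_per_gene[0], cfg.background_reads_per_gene[1] + 1)
        )
        for _ in range(n_bg):
            length = int(rng.integers(lo_l, hi_l + 1))
            start = int(rng.integers(0, tx_len - length + 1))
            reads.append(
                _make_read(
                    ann, gene, seq, start, length, rng,
                    cfg.background_error_rate, crosslink=None, skip=set(),
                )
            )
    reads.sort(key=lambda r: (r.chrom, r.strand, r.start, r.end))
    return reads


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _make_read(
    ann: SyntheticAnnotation,
    gene: str,
    seq: str,
    start: int,
    length: int,
    rng: np.random.Generator,
    error_rate: float,
    crosslink: int | None,
    skip: set[int],
) -> AlignedRead:
    st = ann.structure[gene]
    strand = st["strand"]
    mms: list[tuple[int, str, str]] = []  # (tx_pos, sense_ref, sense_read)
    if crosslink is not None and start <= crosslink < start + length:
        mms.append((crosslink, "T", "C"))
    err = rng.random(length) < error_rate
    for i in np.flatnonzero(err):
        t_pos = start + int(i)
        if t_pos in skip:
            continue
        ref = seq[t_pos]
        alt = str(rng.choice([b for b in BASES if b != ref]))
        mms.append((t_pos, ref, alt))
    # map to genomic forward strand
    tx_len = len(seq)
    if strand == "+":
        g_start = start
        g_mms = [Mismatch(p, r, a) for p, r, a in mms]
        t_positions = tuple(
            start + i for i, b in enumerate(seq[start : start + length]) if b == "T"
        )
    else:
        g_start = tx_len - (start + length)
        g_mms = [
            Mismatch(tx_len - 1 - p, _COMP[r], _COMP[a]) for p, r, a in mms
        ]
        g_mms.sort(key=lambda m: m.pos)
        t_positions = tuple(
            sorted(
                tx_len - 1 - (start + i)
                for i, b in enumerate(seq[start : start + length])
                if b == "T"
            )
        )
    return AlignedRead(
        chrom=st["chrom"],
        strand=strand,
        start=g_start,
        read_len=length,
        mismatches=tuple(sorted(g_mms, key=lambda m: m.pos)),
        t_positions=t_positions,
    )


def simulate_counts(cfg: SimConfig, truth: TruthTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix for sponge / control / other-sponge samples.

    Per-gene baseline means are log-normal (median ``baseline_median``);
    variance = mu + dispersion * mu^2.  Target genes are derepressed
    (mean × 2^target_log2fc) in target-sponge samples only; the
    non-targeting "other" sponge carries no planted effect.  Returns
    (counts, sample sheet).
    """
    genes = sorted(truth.records)
    rng_base = cfg.rng(200)
    mu = cfg.baseline_median * np.exp(
        rng_base.normal(0.0, cfg.baseline_log_sigma, size=len(genes))
    )
    samples = []
    for i in range(cfg.n_sponge_samples):
        samples.append((f"sponge_{i + 1}", "target_sponge", i + 1))
    for i in range(cfg.n_control_samples):
        samples.append((f"control_{i + 1}", "control_sponge", i + 1))
    for i in range(cfg.n_other_samples):
        samples.append((f"other_{i + 1}", "other_sponge", i + 1))
    sheet = pd.DataFrame(samples, columns=["sample", "condition", "replicate"]).set_index(
        "sample"
    )

    is_target = np.array([truth.is_target(g) for g in genes])
    fold = 2.0 ** np.array(
        [truth.records[g]["true_log2fc"] for g in genes]
    )
    rng = cfg.rng(201)
    cols = {}
    for sample, cond, _rep in samples:
        mean = np.where(is_target & (cond == "target_sponge"), mu * fold, mu)
        cols[sample] = _nb_draw(rng, mean, cfg.nb_dispersion)
    counts = pd.DataFrame(cols, index=genes)
    counts.index.name = "gene_id"
    return counts, sheet


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# Dataset writer


def write_dataset(cfg: SimConfig, outdir: str | os.PathLike) -> dict:
    """Generate and write a complete dataset directory; returns the objects.

    Files: genome.fa, transcripts.bed, parclip_rep<i>.tsv, counts.tsv,
    samples.tsv, truth.tsv.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    ann = make_annotation(cfg)
    truth = plant_sites(cfg, ann)
    write_fasta(ann.genome(), os.path.join(outdir, "genome.fa"))
    write_bed12(ann.transcripts, os.path.join(outdir, "transcripts.bed"))
    replicas = []
    for r in range(cfg.parclip_replicas):
        reads = simulate_parclip(cfg, ann, truth, r)
        write_alignments_tsv(reads, os.path.join(outdir, f"parclip_rep{r + 1}.tsv"))
        replicas.append(reads)
    counts, sheet = simulate_counts(cfg, truth)
    counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
    sheet.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t")
    truth.to_tsv(os.path.join(outdir, "truth.tsv"))
    return {
        "annotation": ann,
        "truth": truth,
        "replicas": replicas,
        "counts": counts,
        "samples": sheet,
    }
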