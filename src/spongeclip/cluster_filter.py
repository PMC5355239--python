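"""Post-caller cluster filters and replicate overlap analysis.

Mirrors the post-processing applied after cluster calling: clusters are
restricted to 3'UTRs, required to contain a (non-6mer) miRNA seed match
within ±3 bp of the mode location, and a gene counts as a PAR-CLIP hit for
a seed family only when supported by at least two replicas.  Seed matches
live in 3'UTR (transcript) coordinates and are projected onto the genome
through the gene's 3'UTR interval map before windowing, because clusters
are genomic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import pandas as pd

from .annotation import GenomicInterval
from .parclip import Cluster
from .seeds import SeedMatch


class FilterError(ValueError):
    pass


@dataclass(frozen=True)
class FilterConfig:
    restrict_to_3utr: bool = True
    seed_mode_window_nt: int = 3
    exclude_6mer: bool = True
    min_cluster_overlap_bp: int = 10
    min_replicas_for_hit: int = 2
    # "intersect": seed interval intersects the ±window around the mode;
    # "start": the seed start must lie within the window.
    window_mode: str = "intersect"
    # "pairwise": every pair of grouped clusters overlaps >= threshold;
    # "core": the common intersection of the group is >= threshold.
    overlap_mode: str = "pairwise"

    def __post_init__(self) -> None:
        if self.seed_mode_window_nt < 0:
            raise FilterError("seed_mode_window_nt must be >= 0")
        if self.min_cluster_overlap_bp < 1:
            raise FilterError("min_cluster_overlap_bp must be >= 1")
        if self.window_mode not in ("intersect", "start"):
            raise FilterError("window_mode must be 'intersect' or 'start'")
        if self.overlap_mode not in ("pairwise", "core"):
            raise FilterError("overlap_mode must be 'pairwise' or 'core'")


@dataclass(frozen=True)
class FilteredCluster:
    """A cluster that passed the 3'UTR and seed-proximity filters."""

    cluster: Cluster
    matches: tuple[SeedMatch, ...]

    @property
    def gene_id(self) -> str:
        return self.cluster.gene_id

    @property
    def families(self) -> frozenset[str]:
        return frozenset(m.family_id for m in self.matches)

    @property
    def site_types(self) -> frozenset[str]:
        return frozenset(m.site_type for m in self.matches)


def filter_utr3(clusters: Sequence[Cluster]) -> list[Cluster]:
    """Keep only clusters annotated to 3'UTRs (annotate first)."""
    for c in clusters:
        if c.region_label is None:
            raise FilterError(
                "cluster lacks a region label; run annotate_clusters first"
            )
    return [c for c in clusters if c.region_label == "3UTR"]


def utr_match_to_genomic(
    match: SeedMatch, utr_intervals: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """Project a UTR-offset seed match onto genomic intervals.

    ``utr_intervals`` is the gene's merged 3'UTR in genomic order; the
    transcript reads them left-to-right on + and right-to-left (reverse
    complemented) on −.  A match spanning an exon junction yields multiple
    genomic pieces.
    """
    if not utr_intervals:
        raise FilterError(f"gene {match.gene_id}: no 3'UTR intervals for projection")
    strand = utr_intervals[0].strand
    ordered = (
        list(utr_intervals) if strand == "+" else list(reversed(utr_intervals))
    )
    pieces: list[tuple[int, int]] = []
    offset = match.utr_offset
    remaining = match.length
    consumed = 0
    for iv in ordered:
        ln = iv.length
        if offset >= consumed + ln:
            consumed += ln
            continue
        local = max(0, offset - consumed)
        take = min(ln - local, remaining)
        if strand == "+":
            g_start = iv.start + local
            pieces.append((g_start, g_start + take))
        else:
            g_end = iv.end - local
            pieces.append((g_end - take, g_end))
        remaining -= take
        consumed += ln
        offset = consumed  # continue from the start of the next interval
        if remaining <= 0:
            break
    if remaining > 0:
        raise FilterError(
            f"gene {match.gene_id}: seed match at UTR offset {match.utr_offset} "
            "extends past the 3'UTR"
        )
    return pieces


def seed_proximity_filter(
    clusters: Sequence[Cluster],
    matches_by_gene: Mapping[str, Sequence[SeedMatch]],
    utr_by_gene: Mapping[str, Sequence[GenomicInterval]],
    cfg: FilterConfig,
) -> list[FilteredCluster]:
    """Retain clusters with a seed match within ±window of the mode location.

    A cluster passes when at least one (non-6mer, if ``exclude_6mer``) seed
    match in its gene's 3'UTR lies within ``seed_mode_window_nt`` of the
    mode location — by default the match *interval* must intersect
    [mode − w, mode + w]; with ``window_mode='start'`` the match start
    position must fall inside the window.
    """
    out = []
    w = cfg.seed_mode_window_nt
    for c in clusters:
        if c.gene_id is None:
            continue
        utr = utr_by_gene.get(c.gene_id, ())
        kept: list[SeedMatch] = []
        for m in matches_by_gene.get(c.gene_id, ()):
            if cfg.exclude_6mer and m.site_type == "6mer":
                continue
            for g_start, g_end in utr_match_to_genomic(m, utr):
                if cfg.window_mode == "intersect":
                    hit = g_start <= c.mode_location + w and g_end > c.mode_location - w
                else:
                    hit = abs(g_start - c.mode_location) <= w
                if hit:
                    kept.append(m)
                    break
        if kept:
            out.append(FilteredCluster(c, tuple(kept)))
    return out


# ---------------------------------------------------------------------------
# Replicate overlap


def gene_overlap(replica_gene_sets: Sequence[set[str]]) -> dict:
    """Gene-level replicate overlap.

    Pairwise shared fractions are computed with respect to the smaller set;
    ``genes_in_all`` is the intersection across every replica.
    """
    if len(replica_gene_sets) < 2:
        raise FilterError("gene_overlap needs >= 2 replicas")
    sizes = [len(s) for s in replica_gene_sets]
    pairwise = {}
    for (i, a), (j, b) in combinations(enumerate(replica_gene_sets), 2):
        shared = len(a & b)
        smaller = min(len(a), len(b))
        pairwise[(i, j)] = {
            "shared": shared,
            "fraction_of_smaller": shared / smaller if smaller else 0.0,
        }
    genes_in_all = frozenset.intersection(*(frozenset(s) for s in replica_gene_sets))
    return {"sizes": sizes, "pairwise": pairwise, "genes_in_all": genes_in_all}


def _pairwise_ok(spans: Sequence[Cluster], min_bp: int) -> bool:
    return all(
        min(a.end, b.end) - max(a.start, b.start) >= min_bp
        for a, b in combinations(spans, 2)
    )


def _core_ok(spans: Sequence[Cluster], min_bp: int) -> bool:
    lo = max(c.start for c in spans)
    hi = min(c.end for c in spans)
    return hi - lo >= min_bp


def cluster_overlap(
    replicas: Sequence[Sequence[Cluster]], cfg: FilterConfig
) -> list[tuple[Cluster, ...]]:
    """Groups of mutually overlapping clusters, one per replica.

    A group is reported when one cluster from each replica overlaps every
    other by at least ``min_cluster_overlap_bp`` (or, in 'core' mode, their
    common intersection reaches that length).  Each cluster joins at most
    one group; candidates are resolved greedily left-to-right, which makes
    the result deterministic.
    """
    if len(replicas) < 2:
        raise FilterError("cluster_overlap needs >= 2 replicas")
    ok = _pairwise_ok if cfg.overlap_mode == "pairwise" else _core_ok
    sorted_reps = [
        sorted(r, key=lambda c: (c.chrom, c.start, c.end)) for r in replicas
    ]
    used = [set() for _ in sorted_reps]
    groups: list[tuple[Cluster, ...]] = []

    def extend(chosen: list[Cluster], rep_idx: int) -> tuple[Cluster, ...] | None:
        if rep_idx == len(sorted_reps):
            return tuple(chosen)
        for k, cand in enumerate(sorted_reps[rep_idx]):
            if k in used[rep_idx] or cand.chrom != chosen[0].chrom:
                continue
            if cand.strand != chosen[0].strand:
                continue
            if ok(chosen + [cand], cfg.min_cluster_overlap_bp):
                result = extend(chosen + [cand], rep_idx + 1)
                if result is not None:
                    used[rep_idx].add(k)
                    return result
        return None

    for i, anchor in enumerate(sorted_reps[0]):
        if i in used[0]:
            continue
        result = extend([anchor], 1)
        if result is not None:
            used[0].add(i)
            groups.append(result)
    return groups


def gene_hit_table(
    replicas: Sequence[Sequence[FilteredCluster]], cfg: FilterConfig
) -> pd.DataFrame:
    """Per gene × seed family: replica support and the >=2-replica hit flag.

    Rows cover every (gene, family) pair seen in any filtered cluster of
    any replica.  Columns: gene_id, family_id, n_replicas, replicas
    (comma-joined indices), site_types (comma-joined), hit.
    """
    if len(replicas) < 2:
        raise FilterError("gene_hit_table needs >= 2 replicas")
    support: dict[tuple[str, str], dict] = {}
    for ridx, rep in enumerate(replicas):
        for fc in rep:
            for m in fc.matches:
                rec = support.setdefault(
                    (fc.gene_id, m.family_id), {"replicas": set(), "site_types": set()}
                )
                rec["replicas"].add(ridx)
                rec["site_types"].add(m.site_type)
    rows = []
    for (gene, family), rec in sorted(support.items()):
        n = len(rec["replicas"])
        rows.append(
            {
                "gene_id": gene,
                "family_id": family,
                "n_replicas": n,
                "replicas": ",".join(str(r) for r in sorted(rec["replicas"])),
                "site_types": ",".join(sorted(rec["site_types"])),
                "hit": n >= cfg.min_replicas_for_hit,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "family_id", "n_replicas", "replicas", "site_types", "hit"],
    )


def hit_genes(hit_table: pd.DataFrame, families: Sequence[str] | None = None) -> set[str]:
    """Genes with a >=2-replica hit, optionally restricted to given families."""
    t = hit_table[hit_table["hit"]]
    if families is not None:
        t = t[t["family_id"].isin(list(families))]
    return set(t["gene_id"])
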