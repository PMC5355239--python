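"""End-to-end orchestration: simulate → call → filter → DE → intersect.

``run_all`` executes the whole targetome inference on a synthetic dataset
with known truth and writes every stage output plus a run report whose
record counts form a monotone filter funnel.  The stage functions are also
usable individually (and are what the command-line interface wraps).
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field, replace

import pandas as pd
import yaml

from . import __version__
from .annotation import RegionSet, SequenceStore, load_fasta, load_transcripts, derive_all_regions, utr3_sequence
from .cluster_filter import (
    FilterConfig,
    filter_utr3,
    gene_hit_table,
    gene_overlap,
    cluster_overlap,
    seed_proximity_filter,
)
from .de import DEConfig, call_de, cpm_filter, de_test, load_counts, specificity_screen
from .enrich import intersect_targets, seed_enrichment, write_target_calls
from .parclip import (
    ParclipConfig,
    apply_read_filters,
    call_all_clusters,
    annotate_clusters,
    mutation_profile,
    read_alignments_tsv,
    write_clusters_bed,
)
from .seeds import default_families, load_family_table, scan_utr
from .simulate import SimConfig, write_dataset

log = logging.getLogger("spongeclip")


@dataclass(frozen=True)
class PipelineConfig:
    parclip: ParclipConfig = field(default_factory=ParclipConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    de: DEConfig = field(default_factory=DEConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    family_table: str | None = None  # None -> shipped default table
    families_of_interest: tuple[str, ...] | None = None  # None -> planted families

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {"parclip", "filters", "de", "sim", "family_table", "families_of_interest"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(
                f"unknown config section(s) {sorted(unknown)}; valid: {sorted(known)}"
            )

        def build(cls_, key):
            section = raw.get(key, {}) or {}
            valid = set(cls_.__dataclass_fields__)
            bad = set(section) - valid
            if bad:
                raise ValueError(
                    f"unknown key(s) {sorted(bad)} in [{key}]; valid: {sorted(valid)}"
                )
            section = {
                k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
            }
            return cls_(**section)

        return cls(
            parclip=build(ParclipConfig, "parclip"),
            filters=build(FilterConfig, "filters"),
            de=build(DEConfig, "de"),
            sim=build(SimConfig, "sim"),
            family_table=raw.get("family_table"),
            families_of_interest=(
                tuple(raw["families_of_interest"])
                if raw.get("families_of_interest")
                else None
            ),
        )

    def to_yaml(self, path: str | os.PathLike) -> None:
        data = {
            "parclip": asdict(self.parclip),
            "filters": asdict(self.filters),
            "de": asdict(self.de),
            "sim": asdict(self.sim),
            "family_table": self.family_table,
            "families_of_interest": (
                list(self.families_of_interest) if self.families_of_interest else None
            ),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunReport:
    """Per-stage record counts and run metadata."""

    counts: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    rng_seed: int | None = None

    def add(self, stage: str, n: int) -> None:
        self.counts[stage] = int(n)
        log.info("%-40s %d", stage, n)

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcount\n")
            for stage, n in self.counts.items():
                fh.write(f"{stage}\t{n}\n")
            fh.write(f"#version\t{self.version}\n")
            fh.write(f"#rng_seed\t{self.rng_seed}\n")


def _families(cfg: PipelineConfig):
    if cfg.family_table:
        return load_family_table(cfg.family_table)
    return default_families()


def scan_all_utrs(store: SequenceStore, regions: RegionSet, families, include_6mer=False):
    """Seed matches per gene over every annotated 3'UTR."""
    matches = {}
    for gene in sorted(regions.utr3_by_gene()):
        seq = utr3_sequence(gene, store, regions)
        found = scan_utr(seq, families, gene_id=gene, include_6mer=include_6mer)
        if found:
            matches[gene] = found
    return matches


def run_all(cfg: PipelineConfig, outdir: str | os.PathLike, seed: int | None = None) -> dict:
    """Run simulate → callclusters → filterclusters → de → enrich → intersect.

    Returns a dict with every intermediate object, the report, and the
    recall/precision of the final target calls against the planted truth.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    sim = cfg.sim if seed is None else replace(cfg.sim, rng_seed=seed)
    report = RunReport(rng_seed=sim.rng_seed)
    log.info("spongeclip %s: full synthetic run (seed=%s)", __version__, sim.rng_seed)

    data = write_dataset(sim, os.path.join(outdir, "data"))
    ann, truth = data["annotation"], data["truth"]
    store = ann.sequence_store()
    regions = ann.regions()
    families = _families(cfg)
    utr_by_gene = regions.utr3_by_gene()
    matches_by_gene = scan_all_utrs(store, regions, families)
    report.add("genes_simulated", sim.n_genes)
    report.add("genes_with_seed_matches", len(matches_by_gene))

    filtered_by_replica = []
    clusters_by_replica = []
    profiles = []
    for r, raw_reads in enumerate(data["replicas"]):
        tag = f"rep{r + 1}"
        report.add(f"{tag}.reads_in", len(raw_reads))
        profiles.append(mutation_profile(raw_reads))
        reads = apply_read_filters(raw_reads, cfg.parclip)
        report.add(f"{tag}.reads_after_filters", len(reads))
        clusters = call_all_clusters(reads, cfg.parclip, replica=tag)
        report.add(f"{tag}.clusters_called", len(clusters))
        annotated, occupancy = annotate_clusters(clusters, regions)
        utr3 = filter_utr3(annotated)
        report.add(f"{tag}.clusters_3utr", len(utr3))
        filtered = seed_proximity_filter(utr3, matches_by_gene, utr_by_gene, cfg.filters)
        report.add(f"{tag}.clusters_seed_proximal", len(filtered))
        write_clusters_bed(annotated, os.path.join(outdir, f"clusters_{tag}.bed"))
        clusters_by_replica.append(annotated)
        filtered_by_replica.append(filtered)
        occ_path = os.path.join(outdir, f"occupancy_{tag}.tsv")
        with open(occ_path, "w") as fh:
            fh.write("region\tpercent\n")
            for lab in sorted(occupancy):
                fh.write(f"{lab}\t{occupancy[lab]:.4f}\n")

    gene_sets_by_rep = [{fc.gene_id for fc in rep} for rep in filtered_by_replica]
    overlap = gene_overlap(gene_sets_by_rep)
    groups = cluster_overlap(
        [[fc.cluster for fc in rep] for rep in filtered_by_replica], cfg.filters
    )
    report.add("genes_in_all_replicas", len(overlap["genes_in_all"]))
    report.add("cluster_groups_all_replicas", len(groups))
    hits = gene_hit_table(filtered_by_replica, cfg.filters)
    hits.to_csv(os.path.join(outdir, "gene_hit_table.tsv"), sep="\t", index=False)
    report.add("gene_family_hits", int(hits["hit"].sum()))

    counts, samples = data["counts"], data["samples"]
    kept = cpm_filter(counts, cfg.de)
    report.add("genes_cpm_filtered", len(kept))
    de_results = de_test(counts.loc[kept], samples, cfg.de)
    de_results.to_csv(os.path.join(outdir, "de_results.tsv"), sep="\t")
    calls = call_de(de_results, cfg.de)
    report.add("de_up_strict", len(calls["up_strict"]))
    report.add("de_down_strict", len(calls["down_strict"]))
    report.add("de_up_relaxed", len(calls["up_relaxed"]))

    other_results = de_test(
        counts.loc[kept], samples, cfg.de, contrast=("other_sponge", "control_sponge")
    )
    other_calls = call_de(other_results, cfg.de)
    specificity = specificity_screen(calls, other_calls, set(kept))

    universe = set(kept)
    enrichment = seed_enrichment(calls["up_relaxed"], hits, universe)
    enrichment.to_csv(os.path.join(outdir, "seed_enrichment.tsv"), sep="\t", index=False)

    families_of_interest = cfg.families_of_interest or sim.planted_families
    target_calls = intersect_targets(
        de_results, hits, families_of_interest, cfg.de.relaxed_log2fc
    )
    write_target_calls(target_calls, os.path.join(outdir, "target_calls.tsv"))
    report.add("target_calls", len(target_calls))

    called = {c.gene_id for c in target_calls}
    true_targets = truth.target_genes
    recall = len(called & true_targets) / len(true_targets) if true_targets else 0.0
    precision = len(called & true_targets) / len(called) if called else 0.0
    report.to_tsv(os.path.join(outdir, "run_report.tsv"))

    return {
        "config": cfg,
        "report": report,
        "annotation": ann,
        "truth": truth,
        "profiles": profiles,
        "clusters_by_replica": clusters_by_replica,
        "filtered_by_replica": filtered_by_replica,
        "gene_overlap": overlap,
        "cluster_groups": groups,
        "hit_table": hits,
        "de_results": de_results,
        "de_calls": calls,
        "specificity": specificity,
        "enrichment": enrichment,
        "target_calls": target_calls,
        "recall": recall,
        "precision": precision,
    }


# ---------------------------------------------------------------------------
# File-based stage runners (CLI backends)


def stage_callclusters(alignments, annotation_path, fasta_path, cfg: ParclipConfig, out_prefix):
    """Cluster calling from an alignment file against an annotation + genome."""
    from .parclip import ingest_alignments

    transcripts = load_transcripts(annotation_path)
    regions = derive_all_regions(transcripts)
    store = load_fasta(fasta_path)
    reads = ingest_alignments(alignments, cfg, reference=store)
    clusters = call_all_clusters(reads, cfg)
    annotated, occupancy = annotate_clusters(clusters, regions)
    write_clusters_bed(annotated, f"{out_prefix}.clusters.bed")
    return annotated, occupancy


def stage_de(counts_path, samples_path, cfg: DEConfig, out_path, contrast=("target_sponge", "control_sponge")):
    counts, samples = load_counts(counts_path, samples_path)
    kept = cpm_filter(counts, cfg)
    results = de_test(counts.loc[kept], samples, cfg, contrast=contrast)
    results.to_csv(out_path, sep="\t")
    return results
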