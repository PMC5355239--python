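"""Call PAR-CLIP clusters from simulated AGO2 reads and annotate them.

Reads are chained into overlap groups; Gaussian kernel densities of T→C
conversion vs. non-conversion evidence (bandwidth 3 nt) define cluster
intervals, extended to read boundaries; clusters are then assigned to gene
regions by maximal overlap.
"""

from spongeclip.parclip import (
    ParclipConfig,
    annotate_clusters,
    apply_read_filters,
    call_all_clusters,
    mutation_profile,
)
from spongeclip.simulate import SimConfig, make_annotation, plant_sites, simulate_parclip

sim = SimConfig(rng_seed=1, n_genes=100, n_true_targets=15)
ann = make_annotation(sim)
truth = plant_sites(sim, ann)
raw_reads = simulate_parclip(sim, ann, truth, replica_index=0)

profile = mutation_profile(raw_reads)
print(f"reads: {len(raw_reads)}; T>C share of all mismatches: {profile['T>C']:.1f}%")

cfg = ParclipConfig()  # bandwidth 3, min 5 reads, min cluster size 10, T>C only
reads = apply_read_filters(raw_reads, cfg)
clusters = call_all_clusters(reads, cfg)
annotated, occupancy = annotate_clusters(clusters, ann.regions())

print(f"{len(clusters)} clusters called; region occupancy (% of clusters):")
for label, pct in sorted(occupancy.items(), key=lambda kv: -kv[1]):
    print(f"  {label:10s} {pct:5.1f}%")
c = annotated[0]
print(
    f"example cluster: {c.chrom}:{c.start}-{c.end} ({c.strand}), "
    f"{c.read_count} reads, {c.conversion_count} conversions, mode at {c.mode_location}"
)
print(
    "A high T>C share and 3'UTR-dominated occupancy are the hallmarks of "
    "specific AGO2 crosslinking; the mode location marks the crosslink site."
)
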