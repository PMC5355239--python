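"""Derive seed motifs from mature miRNA sequences and scan a 3'UTR.

Seed motifs are reported in miRNA 5'→3' orientation (positions 2–8) and
matched on the UTR sense strand via reverse complement.  Site types follow
the canonical hierarchy: 8mer > 7mer-m8 / 7mer-A1 > 6mer (6mers are
excluded from downstream analyses).
"""

from spongeclip.seeds import default_families, derive_seed, scan_utr, site_pattern

mir17_mature = "CAAAGUGCUUACAGUGCAGGUAG"  # hsa-miR-17-5p
print("miR-17-5p seed (positions 2-8):", derive_seed(mir17_mature, 2, 8))

families = default_families()
for fam in families:
    print(f"{fam.family_id:15s} motif7={fam.motif7} -> 8mer target site {site_pattern(fam, '8mer')}")

utr = "AAGGCAGCACTTTATCGGATTTGCACAATCGGGCACTTTGCC"
for m in scan_utr(utr, families):
    print(
        f"site: {m.site_type:8s} of {m.family_id:15s} at UTR offset {m.utr_offset} "
        f"({utr[m.utr_offset:m.utr_end]})"
    )
print(
    "The 8mer at offset 6 pairs with miR-17 positions 2-8 plus the A1 adenosine; "
    "the 7mer-m8 lacks the A.  These typed sites feed the cluster seed-proximity filter."
)
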