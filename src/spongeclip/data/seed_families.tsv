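family_id	motif7	motif8	members
mir-17_family	AAAGTGC	TAAAGTGC	hsa-miR-17-5p;hsa-miR-20a-5p;hsa-miR-106a-5p;hsa-miR-106b-5p;hsa-miR-20b-5p
mir-18_family	AAGTGCA	AAGTGCAT	hsa-miR-18a-5p;hsa-miR-18b-5p
mir-19_family	GTGCAAA	TGTGCAAA	hsa-miR-19a-3p;hsa-miR-19b-3p
mir-92_family	ATTGCAC	TATTGCAC	hsa-miR-92a-3p;hsa-miR-92b-3p
mir-9_family	CTTTGGT	TCTTTGGT	hsa-miR-9-5p
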