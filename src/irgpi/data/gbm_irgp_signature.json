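{
  "pairs": [
    {"gene_a": "HSPA6", "gene_b": "BMP2", "coefficient": 0.464,
     "category_a": "Antigen Processing and Presentation", "category_b": "TGFb Family Member"},
    {"gene_a": "PSMC3", "gene_b": "MDK", "coefficient": -0.358,
     "category_a": "Antigen Processing and Presentation", "category_b": "Cytokines"},
    {"gene_a": "FGF2", "gene_b": "OSMR", "coefficient": -0.460,
     "category_a": "Antimicrobials", "category_b": "Cytokine Receptors"},
    {"gene_a": "PPP4C", "gene_b": "MDK", "coefficient": -0.293,
     "category_a": "Antimicrobials", "category_b": "Cytokines"},
    {"gene_a": "LEFTY2", "gene_b": "MSTN", "coefficient": 0.555,
     "category_a": "Cytokines", "category_b": "Cytokines"}
  ],
  "cutoff": 0.197
}
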