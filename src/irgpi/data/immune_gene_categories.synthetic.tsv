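gene	category
HSPA6	Antigen Processing and Presentation
PSMC3	Antigen Processing and Presentation
TAP1	Antigen Processing and Presentation
HLA-A	Antigen Processing and Presentation
B2M	Antigen Processing and Presentation
BMP2	TGFb Family Member
TGFB1	TGFb Family Member
GDF15	TGFb Family Member
INHBA	TGFb Family Member
MDK	Cytokines
LEFTY2	Cytokines
MSTN	Cytokines
IL6	Cytokines
TNF	Cytokines
IFNG	Cytokines
OSM	Cytokines
OSMR	Cytokine Receptors
IL6R	Cytokine Receptors
IFNGR1	Cytokine Receptors
CSF1R	Cytokine Receptors
FGF2	Antimicrobials
PPP4C	Antimicrobials
CAMP	Antimicrobials
DEFB1	Antimicrobials
LTF	Antimicrobials
CXCL9	Chemokines
CXCL10	Chemokines
CCL2	Chemokines
CCL22	Chemokines
CXCR3	Chemokine Receptors
CCR5	Chemokine Receptors
CCR7	Chemokine Receptors
IFNA1	Interferons
IFNB1	Interferons
IFNAR1	Interferon Receptors
IFNGR2	Interferon Receptors
IL2	Interleukins
IL10	Interleukins
IL17A	Interleukins
IL1B	Interleukins
IL2RA	Interleukin Receptors
IL7R	Interleukin Receptors
IL23R	Interleukin Receptors
GZMB	Natural Killer Cell Cytotoxicity
PRF1	Natural Killer Cell Cytotoxicity
KLRD1	Natural Killer Cell Cytotoxicity
NCR1	Natural Killer Cell Cytotoxicity
CD19	BCR Signaling Pathway
CD79A	BCR Signaling Pathway
BLNK	BCR Signaling Pathway
CD3E	TCR Signaling Pathway
ZAP70	TCR Signaling Pathway
LCK	TCR Signaling Pathway
TGFBR1	TGFb Family Member Receptor
TGFBR2	TGFb Family Member Receptor
TNFSF10	TNF Family Members
CD40LG	TNF Family Members
FASLG	TNF Family Members
TNFRSF9	TNF Family Receptors
TNFRSF18	TNF Family Receptors
CD40	TNF Family Receptors
CD274	Immune Checkpoint
CTLA4	Immune Checkpoint
PDCD1	Immune Checkpoint
LAG3	Immune Checkpoint
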