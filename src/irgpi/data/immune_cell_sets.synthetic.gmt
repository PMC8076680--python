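Activated CD4 T cell	CD4 T cell	CD4	IL2RA	CD69	ICOS	TNFRSF9	CD40LG
Central memory CD4 T cell	CD4 T cell	CD4	CCR7	SELL	IL7R	TCF7	CD27
Effector memory CD4 T cell	CD4 T cell	CD4	GZMA	KLRG1	CCR5	PRDM1	IFNG
Activated CD8 T cell	CD8 T cell	CD8A	CD8B	GZMB	PRF1	CD69	TNFRSF9
Central memory CD8 T cell	CD8 T cell	CD8A	CCR7	SELL	IL7R	TCF7	CD28
Effector memory CD8 T cell	CD8 T cell	CD8A	GZMK	KLRG1	EOMES	CX3CR1	GZMH
Type 1 T helper cell	T helper cell	TBX21	IFNG	IL12RB2	STAT4	CXCR3	IL2
Type 2 T helper cell	T helper cell	GATA3	IL4	IL5	IL13	CCR4	STAT6
Type 17 T helper cell	T helper cell	RORC	IL17A	IL17F	IL22	CCR6	IL23R
T follicular helper cell	T helper cell	BCL6	CXCR5	PDCD1	IL21	ICOS	SH2D1A
Regulatory T cell	Regulatory T cell	FOXP3	IL2RA	CTLA4	IKZF2	TNFRSF18	IL10
Gamma delta T cell	Gamma delta T cell	TRGC1	TRDC	TRGC2	KLRC1	NCR3	CD160
Activated B cell	B cell	CD19	MS4A1	CD79A	CD79B	CD86	TNFRSF13B
Immature B cell	B cell	CD19	IGHM	CD38	VPREB1	IGLL1	RAG1
Memory B cell	B cell	CD19	CD27	CD40	TNFRSF13C	AIM2	SPIB
Natural killer cell	NK cell	NCAM1	NKG7	KLRD1	NCR1	KIR2DL1	GNLY
CD56bright natural killer cell	NK cell	NCAM1	SELL	XCL1	XCL2	KLRC1	GZMK
CD56dim natural killer cell	NK cell	FCGR3A	GZMB	PRF1	KIR2DL3	CX3CR1	SPON2
Natural killer T cell	NKT cell	ZBTB16	CD1D	KLRB1	IL18RAP	GZMA	SLAMF1
Activated dendritic cell	Dendritic cell	CD83	CD80	CD86	CCR7	LAMP3	IL12B
Immature dendritic cell	Dendritic cell	CD1A	CD1C	ITGAX	FCER1A	CLEC10A	MRC1
Plasmacytoid dendritic cell	Dendritic cell	CLEC4C	LILRA4	IL3RA	IRF7	TCF4	GZMB
Macrophage M1	Macrophage	NOS2	IL1B	TNF	CXCL9	CXCL10	SOCS3
Macrophage M2	Macrophage	CD163	MRC1	MSR1	IL10	CCL22	ARG1
Monocyte	Monocyte	CD14	LYZ	FCN1	S100A8	S100A9	VCAN
Neutrophil	Neutrophil	FCGR3B	CSF3R	CXCR2	FPR1	MPO	ELANE
Eosinophil	Eosinophil	SIGLEC8	CCR3	IL5RA	PRG2	EPX	RNASE2
Mast cell	Mast cell	KIT	TPSAB1	TPSB2	CPA3	MS4A2	HDC
MDSC	MDSC	ITGAM	ARG1	S100A8	S100A9	OLR1	IL4R
Basophil	Basophil	MS4A2	ENPP3	HDC	CCR3	IL3RA	GATA2
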