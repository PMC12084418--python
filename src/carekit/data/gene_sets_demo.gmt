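REACTOME_SIGNALING_BY_FGFR_IN_DISEASE	synthetic demo set	FGFR1	FGFR2	FGFR3	FGFR4	FRS2	PLCG1	SOS1	GRB2
BIOCARTA_PDGF_PATHWAY	synthetic demo set	PDGFRA	PDGFRB	ELK1	MAP2K2	STAT2	RAF1	SHC1	JAK1
HALLMARK_G2M_CHECKPOINT	synthetic demo set	CCND2	CDK4	CDK6	CCNB1	CDC20	PLK1	AURKA	BUB1
HALLMARK_ANGIOGENESIS	synthetic demo set	VEGFA	KDR	FGF2	PDGFA	ANGPT1	TEK
KRAS_SIGNALING	synthetic demo set	KRAS	BRAF	MAP2K1	MAPK1	EGFR	ERBB2
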