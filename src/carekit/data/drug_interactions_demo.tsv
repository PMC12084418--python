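gene	drug	source	interaction_type
FGFR1	pazopanib	CIViC	inhibitor
FGFR2	pazopanib	CIViC	inhibitor
PDGFRA	pazopanib	My Cancer Genome	inhibitor
PDGFRA	imatinib	CIViC	inhibitor
CCND2	ribociclib	CIViC	inhibitor (CDK4/6 axis)
CDK4	ribociclib	My Cancer Genome	inhibitor
CDK4	palbociclib	My Cancer Genome Clinical Trial	inhibitor
CDK6	ribociclib	My Cancer Genome Clinical Trial	inhibitor
VEGFA	pazopanib	Cancer Commons	inhibitor
KDR	pazopanib	Cancer Commons	inhibitor
ERBB2	trastuzumab	CIViC	antibody
EGFR	erlotinib	My Cancer Genome	inhibitor
BRAF	vemurafenib	CIViC	inhibitor
TP53	unproven-compound	NonCuratedSource	unknown
MYC	unproven-compound	NonCuratedSource	unknown
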