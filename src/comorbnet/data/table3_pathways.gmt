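hsa04659	Th17 cell differentiation	CD4	LCK	MAPK14	NFKBIA	RELA	STAT3	TGFB1	TGFBR1	TGFBR2	ZAP70
hsa04940	Type I diabetes mellitus	TNF
hsa04658	Th1 and Th2 cell differentiation	CD4	LCK	MAPK14	NFKBIA	RELA	ZAP70
hsa04064	NF-kappa B signaling pathway	BIRC2	LCK	NFKBIA	RELA	SYK	TNF	TRAF2	UBE2I	ZAP70
hsa04210	Apoptosis	BIRC2	CASP3	CASP8	NFKBIA	PIK3R1	RELA	TNF	TRAF2
hsa04668	TNF signaling pathway	BIRC2	CASP3	CASP8	MAPK14	NFKBIA	PIK3R1	RELA	TNF	TRAF2
hsa04060	Cytokine-cytokine receptor interaction	CCR5	EGFR	IL18	TGFB1	TGFBR1	TGFBR2	TNF
hsa04660	T cell receptor signaling pathway	CBLB	CD4	CTLA4	FYN	LCK	MAPK14	NFKBIA	PIK3R1	RELA	TNF	ZAP70
hsa04620	Toll-like receptor signaling pathway	CASP8	MAPK14	NFKBIA	PIK3R1	RELA	TNF
hsa04010	MAPK signaling pathway	ARRB1	CASP3	EGFR	IGF1R	MAPK14	RELA	TGFB1	TGFBR1	TGFBR2	TNF	TRAF2
hsa04910	Insulin signaling pathway	CBL	CBLB	PIK3R1	SHC1
hsa04630	Jak-STAT signaling pathway	CREBBP	EGFR	PIK3R1	PTPN11	STAT3
hsa04151	PI3K-Akt signaling pathway	EGFR	IGF1R	PIK3R1	RELA	SYK
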