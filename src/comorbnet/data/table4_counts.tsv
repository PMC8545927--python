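protein	n_mirnas
AGT	0
AGTR1	2
APP	11
ARRB1	4
BIRC2	6
CASP1	2
CASP3	10
CASP8	5
CAV1	7
CBL	8
CBLB	2
CCR5	3
CD4	3
CDC5L	3
CREBBP	4
CTLA4	1
CTNNB1	14
EGFR	12
ESR1	7
FYN	8
IGF1R	14
IL16	1
IL18	5
LCK	1
MAPK14	5
NFKBIA	8
NOS2	1
PIK3R1	8
PRKCD	3
PTPN11	7
RELA	3
SHC1	2
SNCA	6
SRC	4
STAT3	14
SYK	1
TGFB1	6
TGFBR1	9
TGFBR2	12
TNF	3
TOR1A	2
TRAF2	1
UBB	6
UBC	5
UBE2I	3
ZAP70	1
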