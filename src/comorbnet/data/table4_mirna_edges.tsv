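protein	mirna
AGTR1	miR-155-5p
AGTR1	miR-34a-5p
APP	let-7g-3p
APP	miR-103a-3p
APP	miR-148a-3p
APP	miR-155-5p
APP	miR-181a-3p
APP	miR-181a-5p
APP	miR-20a-5p
APP	miR-210-3p
APP	miR-21-3p
APP	miR-23b-3p
APP	miR-34a-3p
ARRB1	miR-146a-5p
ARRB1	miR-155-5p
ARRB1	miR-20a-5p
ARRB1	miR-34a-5p
BIRC2	let-7g-5p
BIRC2	miR-149-5p
BIRC2	miR-20a-5p
BIRC2	miR-210-3p
BIRC2	miR-23b-3p
BIRC2	miR-34a-5p
CASP1	miR-21-3p
CASP1	miR-34a-5p
CASP3	let-7g-5p
CASP3	miR-100-5p
CASP3	miR-1275
CASP3	miR-155-5p
CASP3	miR-20a-3p
CASP3	miR-21-3p
CASP3	miR-23a-3p
CASP3	miR-23b-3p
CASP3	miR-34a-5p
CASP3	miR-375
CASP8	miR-146a-5p
CASP8	miR-155-5p
CASP8	miR-20a-5p
CASP8	miR-21-5p
CASP8	miR-34a-5p
CAV1	miR-103a-3p
CAV1	miR-155-5p
CAV1	miR-192-5p
CAV1	miR-20a-5p
CAV1	miR-210-3p
CAV1	miR-23b-3p
CAV1	miR-24-3p
CBL	let-7g-5p
CBL	miR-146a-5p
CBL	miR-148a-3p
CBL	miR-150-5p
CBL	miR-155-5p
CBL	miR-23a-3p
CBL	miR-23b-3p
CBL	miR-24-3p
CBLB	miR-146a-5p
CBLB	miR-21-3p
CCR5	let-7g-5p
CCR5	miR-103a-3p
CCR5	miR-21-3p
CD4	miR-100-5p
CD4	miR-181a-5p
CD4	miR-23b-3p
CDC5L	miR-181a-5p
CDC5L	miR-20a-5p
CDC5L	miR-34a-5p
CREBBP	miR-100-5p
CREBBP	miR-103a-3p
CREBBP	miR-20a-3p
CREBBP	miR-24-3p
CTLA4	miR-155-5p
CTNNB1	miR-103a-3p
CTNNB1	miR-155-5p
CTNNB1	miR-181a-5p
CTNNB1	miR-200a-3p
CTNNB1	miR-20a-3p
CTNNB1	miR-210-3p
CTNNB1	miR-21-3p
CTNNB1	miR-21-5p
CTNNB1	miR-23a-3p
CTNNB1	miR-23b-3p
CTNNB1	miR-24-3p
CTNNB1	miR-34a-3p
CTNNB1	miR-34a-5p
CTNNB1	miR-375
EGFR	let-7g-3p
EGFR	miR-103a-3p
EGFR	miR-146a-5p
EGFR	miR-155-5p
EGFR	miR-181a-5p
EGFR	miR-200a-3p
EGFR	miR-21-3p
EGFR	miR-21-5p
EGFR	miR-23a-3p
EGFR	miR-23b-3p
EGFR	miR-24-3p
EGFR	miR-34a-5p
ESR1	miR-100-5p
ESR1	mir-181a
ESR1	miR-192-5p
ESR1	miR-21-5p
ESR1	miR-23a-3p
ESR1	miR-23b-3p
ESR1	miR-24-3p
FYN	let-7g-3p
FYN	miR-155-5p
FYN	miR-20a-5p
FYN	miR-210-3p
FYN	miR-21-5p
FYN	miR-23a-3p
FYN	miR-23b-3p
FYN	miR-34a-5p
IGF1R	let-7g-3p
IGF1R	let-7g-5p
IGF1R	miR-100-5p
IGF1R	miR-103a-3p
IGF1R	miR-1275
IGF1R	miR-148a-3p
IGF1R	miR-181a-5p
IGF1R	miR-192-5p
IGF1R	miR-20a-5p
IGF1R	miR-21-5p
IGF1R	miR-342-3p
IGF1R	miR-34a-3p
IGF1R	miR-34a-5p
IGF1R	miR-375
IL16	miR-155-5p
IL18	miR-103a-3p
IL18	miR-146a-5p
IL18	miR-155-5p
IL18	miR-210-3p
IL18	miR-24-3p
LCK	miR-210-3p
MAPK14	miR-103a-3p
MAPK14	miR-149-5p
MAPK14	miR-155-5p
MAPK14	miR-200a-3p
MAPK14	miR-24-3p
NFKBIA	leg-7g-3p
NFKBIA	miR-155-5p
NFKBIA	miR-200a-3p
NFKBIA	miR-20a-5p
NFKBIA	miR-21-3p
NFKBIA	miR-23b-3p
NFKBIA	miR-24-3p
NFKBIA	miR-34a-5p
NOS2	miR-146a-5p
PIK3R1	miR-103a-3p
PIK3R1	miR-155-5p
PIK3R1	miR-181a-5p
PIK3R1	miR-20a-5p
PIK3R1	miR-21-5p
PIK3R1	miR-23a-3p
PIK3R1	miR-23b-3p
PIK3R1	miR-487a-3p
PRKCD	miR-155-5p
PRKCD	miR-181a-5p
PRKCD	miR-20a-5p
PTPN11	miR-100-5p
PTPN11	miR-146a-5p
PTPN11	miR-181a-5p
PTPN11	miR-210-3p
PTPN11	miR-21-3p
PTPN11	miR-23a-3p
PTPN11	miR-34a-5p
RELA	miR-155-5p
RELA	miR-24-3p
RELA	miR-34a-4p
SHC1	miR-155-5p
SHC1	miR-200a-3p
SNCA	miR-103a-3p
SNCA	miR-155-5p
SNCA	miR-20a-5p
SNCA	miR-23a-3p
SNCA	miR-23b-3p
SNCA	miR-34a-5p
SRC	miR-146a-5p
SRC	miR-155-5p
SRC	miR-23b-3p
SRC	miR-34a-5p
STAT3	let-7g-5p
STAT3	miR-148a-3p
STAT3	miR-155-5p
STAT3	miR-181a-5p
STAT3	miR-200a-3p
STAT3	miR-20a-3p
STAT3	miR-20a-5p
STAT3	miR-21-3p
STAT3	miR-21-5p
STAT3	miR-210-3p
STAT3	miR-23a-3p
STAT3	miR-23b-3p
STAT3	miR-34a-5p
STAT3	miR-375
SYK	miR-210-3p
TGFB1	miR-103a-3p
TGFB1	miR-146a-5p
TGFB1	miR-21-5p
TGFB1	miR-23b-3p
TGFB1	miR-24-3p
TGFB1	miR-34a-5p
TGFBR1	let-7g-3p
TGFBR1	let-7g-5p
TGFBR1	miR-103a-3p
TGFBR1	miR-148a-3p
TGFBR1	miR-181a-5p
TGFBR1	miR-20a-5p
TGFBR1	miR-210-3p
TGFBR1	miR-21-5p
TGFBR1	miR-34a-3p
TGFBR2	let-7g-3p
TGFBR2	let-7g-5p
TGFBR2	miR-103a-3p
TGFBR2	miR-148a-3p
TGFBR2	miR-155-5p
TGFBR2	miR-181a-5p
TGFBR2	miR-20a-5p
TGFBR2	miR-21-5p
TGFBR2	miR-23a-3p
TGFBR2	miR-23b-3p
TGFBR2	miR-24-3p
TGFBR2	miR-34a-5p
TNF	miR-155-5p
TNF	miR-24-3p
TNF	miR-34a-5p
TOR1A	let-7g-5p
TOR1A	miR-34a-5p
TRAF2	miR-34a-5p
UBB	miR-100-5p
UBB	miR-192-5p
UBB	miR-20a-5p
UBB	miR-23a-3p
UBB	miR-23b-3p
UBB	miR-34a-3p
UBC	miR-155-5p
UBC	miR-20a-5p
UBC	miR-24-3p
UBC	miR-326
UBC	miR-34a-5p
UBE2I	let-7g-5p
UBE2I	miR-181a-5p
UBE2I	miR-34a-5p
ZAP70	miR-34a-5p
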