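# Synthetic stand-in for the curated miRNA--DDR regulatory network.
# The first nine edges are documented in the literature; the remainder
# are deterministic synthetic filler reproducing the published shape
# (142 edges, 75 miRNAs, 55 DDR genes).
mirna	gene	pathway	evidence
mir-24	H2AX	DDS	literature
mir-421	ATM	DDS	literature
mir-146a	BRCA1	HR	literature
mir-151	ARHGDIA	other	literature
mir-421	RAD17	DDS	literature
mir-505*	RAD17	DDS	literature
mir-324	RAD17	DDS	literature
let-7a*	RAD9A	DDS	literature
mir-320	RAD9A	DDS	literature
mir-301b	MSH2	MMR	synthetic
mir-502	MSH3	MMR	synthetic
mir-146a*	ERCC2	NER	synthetic
mir-193a	ATR	DDS	synthetic
mir-21	MSH6	MMR	synthetic
mir-373	MCL1	other	synthetic
mir-29	PRKDC	NHEJ	synthetic
mir-16	XRCC6	NHEJ	synthetic
mir-34	ERCC5	NER	synthetic
mir-214	XRCC4	NHEJ	synthetic
mir-107	AKT1	other	synthetic
mir-222	AKT3	other	synthetic
mir-183	XRCC5	NHEJ	synthetic
mir-96	ATR	DDS	synthetic
mir-182	TP53	DDS	synthetic
let-7a	FANCD2	other	synthetic
mir-901	OGG1	BER	synthetic
mir-902	RAD9A	DDS	synthetic
mir-903	TP53	DDS	synthetic
mir-904	PMS2	MMR	synthetic
mir-905	PMS2	MMR	synthetic
mir-906	BRCA1	HR	synthetic
mir-907	BRIP1	HR	synthetic
mir-908	BRCA1	HR	synthetic
mir-909	RAD9A	DDS	synthetic
mir-910	XPC	NER	synthetic
mir-911	TP53BP1	DDS	synthetic
mir-912	MCL1	other	synthetic
mir-913	H2AX	DDS	synthetic
mir-914	ATR	DDS	synthetic
mir-915	XRCC1	BER	synthetic
mir-916	APEX1	BER	synthetic
mir-917	MRE11A	HR	synthetic
mir-918	XRCC6	NHEJ	synthetic
mir-919	RAD17	DDS	synthetic
mir-920	RAD52	HR	synthetic
mir-921	RAD17	DDS	synthetic
mir-922	RAD23B	NER	synthetic
mir-923	BRCA2	HR	synthetic
mir-924	RAD17	DDS	synthetic
mir-925	TP53	DDS	synthetic
mir-926	TP53BP1	DDS	synthetic
mir-927	ERCC4	NER	synthetic
mir-928	ATR	DDS	synthetic
mir-929	ERCC1	NER	synthetic
mir-930	H2AX	DDS	synthetic
mir-931	UNG	BER	synthetic
mir-932	MDM2	DDS	synthetic
mir-933	ATM	DDS	synthetic
mir-934	MSH6	MMR	synthetic
mir-935	EMSY	HR	synthetic
mir-936	XRCC1	BER	synthetic
mir-937	XPA	NER	synthetic
mir-938	RAD50	HR	synthetic
mir-939	RAD23B	NER	synthetic
mir-940	RAD52	HR	synthetic
mir-941	LIG4	NHEJ	synthetic
mir-942	XRCC1	BER	synthetic
mir-943	PRKDC	NHEJ	synthetic
mir-944	RECQL4	other	synthetic
mir-945	MRE11A	HR	synthetic
mir-946	ERCC3	NER	synthetic
mir-947	MSH3	MMR	synthetic
mir-948	UNG	BER	synthetic
mir-949	RAD23B	NER	synthetic
mir-950	POLB	BER	synthetic
mir-951	RAD17	DDS	synthetic
mir-948	RAD51	HR	synthetic
mir-146a	PALB2	HR	synthetic
mir-24	PTEN	HR	synthetic
mir-107	MLH1	MMR	synthetic
mir-942	PARP1	BER	synthetic
mir-933	CHEK1	DDS	synthetic
mir-948	CHEK2	DDS	synthetic
mir-320	MDC1	DDS	synthetic
mir-911	TOPBP1	DDS	synthetic
mir-943	SIRT1	other	synthetic
mir-909	FANCA	other	synthetic
mir-943	REV1	other	synthetic
mir-29	XRCC6	NHEJ	synthetic
mir-949	LIG4	NHEJ	synthetic
mir-906	PTEN	HR	synthetic
mir-222	POLB	BER	synthetic
mir-936	ATM	DDS	synthetic
mir-918	BRCA2	HR	synthetic
mir-914	RECQL4	other	synthetic
mir-946	ATR	DDS	synthetic
mir-182	PARP1	BER	synthetic
mir-937	XRCC6	NHEJ	synthetic
mir-915	AKT3	other	synthetic
mir-927	PARP1	BER	synthetic
mir-29	XPC	NER	synthetic
mir-919	FANCD2	other	synthetic
mir-320	MSH3	MMR	synthetic
mir-926	ARHGDIA	other	synthetic
mir-909	AKT3	other	synthetic
mir-913	PTEN	HR	synthetic
mir-906	XRCC4	NHEJ	synthetic
mir-930	XPA	NER	synthetic
mir-151	AKT3	other	synthetic
mir-916	RAD52	HR	synthetic
let-7a	ATM	DDS	synthetic
mir-940	ATR	DDS	synthetic
mir-940	XRCC1	BER	synthetic
mir-505*	MDC1	DDS	synthetic
mir-183	MSH3	MMR	synthetic
mir-916	ERCC2	NER	synthetic
mir-96	TP53BP1	DDS	synthetic
let-7a	TOPBP1	DDS	synthetic
mir-936	FANCA	other	synthetic
mir-920	MSH3	MMR	synthetic
mir-324	MDC1	DDS	synthetic
mir-222	MSH6	MMR	synthetic
mir-945	XRCC1	BER	synthetic
mir-918	TOPBP1	DDS	synthetic
mir-911	RECQL4	other	synthetic
mir-944	MRE11A	HR	synthetic
mir-916	LIG4	NHEJ	synthetic
mir-21	ERCC1	NER	synthetic
mir-942	BRCA1	HR	synthetic
mir-949	RECQL4	other	synthetic
mir-915	PTEN	HR	synthetic
mir-906	UNG	BER	synthetic
mir-16	TP53BP1	DDS	synthetic
mir-107	ERCC4	NER	synthetic
mir-921	RAD23B	NER	synthetic
mir-903	XRCC4	NHEJ	synthetic
mir-905	CHEK1	DDS	synthetic
mir-214	RAD51	HR	synthetic
mir-913	BRIP1	HR	synthetic
mir-942	XRCC5	NHEJ	synthetic
mir-911	ERCC5	NER	synthetic
mir-919	XRCC4	NHEJ	synthetic
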