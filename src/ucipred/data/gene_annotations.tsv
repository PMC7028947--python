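gene	role	ddr_pathway
ATM	tumour_suppressor	HR
ATR	tumour_suppressor	checkpoint
BARD1	tumour_suppressor	HR
BRCA1	tumour_suppressor	HR
BRCA2	tumour_suppressor	HR
BRIP1	tumour_suppressor	HR
CHEK1	tumour_suppressor	checkpoint
CHEK2	tumour_suppressor	checkpoint
ERCC2	tumour_suppressor	NER
ERCC3	tumour_suppressor	NER
ERCC4	tumour_suppressor	NER
ERCC5	tumour_suppressor	NER
FANCA	tumour_suppressor	FA
FANCC	tumour_suppressor	FA
FANCD2	tumour_suppressor	FA
MLH1	tumour_suppressor	MMR
MRE11	tumour_suppressor	HR
MSH2	tumour_suppressor	MMR
MSH6	tumour_suppressor	MMR
MUTYH	tumour_suppressor	BER
NBN	tumour_suppressor	HR
PALB2	tumour_suppressor	HR
PMS2	tumour_suppressor	MMR
RAD50	tumour_suppressor	HR
RAD51	tumour_suppressor	HR
RAD51B	tumour_suppressor	HR
RAD51C	tumour_suppressor	HR
RAD51D	tumour_suppressor	HR
XPA	tumour_suppressor	NER
XPC	tumour_suppressor	NER
TP53	tumour_suppressor	none
RB1	tumour_suppressor	none
CDKN2A	tumour_suppressor	none
CDKN2B	tumour_suppressor	none
PTEN	tumour_suppressor	none
KDM6A	tumour_suppressor	none
ARID1A	tumour_suppressor	none
KMT2D	tumour_suppressor	none
KMT2C	tumour_suppressor	none
STAG2	tumour_suppressor	none
TSC1	tumour_suppressor	none
FBXW7	tumour_suppressor	none
ELF3	tumour_suppressor	none
NF1	tumour_suppressor	none
SMAD4	tumour_suppressor	none
FAT1	tumour_suppressor	none
CREBBP	tumour_suppressor	none
EP300	tumour_suppressor	none
FGFR3	oncogene	none
PIK3CA	oncogene	none
ERBB2	oncogene	none
ERBB3	oncogene	none
HRAS	oncogene	none
KRAS	oncogene	none
NRAS	oncogene	none
MDM2	oncogene	none
CCND1	oncogene	none
EGFR	oncogene	none
MYC	oncogene	none
MET	oncogene	none
CDK4	oncogene	none
AKT1	oncogene	none
MYCL	oncogene	none
NOTCH1	both	none
ZFHX3	unknown	none
SPTAN1	unknown	none
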