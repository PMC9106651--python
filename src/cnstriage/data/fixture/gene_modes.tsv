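gene	mode	source
ARX	XL	snv
CC2D2A	AR	snv
DNM1L	AD	snv
FANCC	AR	snv
FGFR3	AD	snv
FOXG1	AD	snv
GJC2	AD	snv
GLI2	AD	snv
KAT6A	AD	cnv_critical
KAT6B	AD	snv
NF1	AD	snv,cnv_critical
NID1	AD	snv
NSD1	AD	snv
OFD1	XLD	snv
PDHA1	XLD	snv
PTCH1	AD	snv
PTPN11	AD	snv
SIX3	AD	snv
SOX2	AD	snv
STIL	AR	snv
TM4SF20	AD	cnv_critical
TUBA1A	AD	snv
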