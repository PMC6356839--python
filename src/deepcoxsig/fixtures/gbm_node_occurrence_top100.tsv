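gene_id	frequency
TNR	17
GAD1	16
TMSB15B	15
POSTN	15
SCG3	15
PLA2G2A	14
NNMT	13
CHI3L1	13
ELAVL4	13
TF	13
UGT8	13
AQP1	12
COL6A3	12
ERBB3	12
KCNQ2	12
LTF	12
MEOX2	12
PCDH9	12
STMN2	12
FCGR2B	11
FGFR3	11
SLC1A2	11
CA10	10
CXCL14	10
CXorf57	10
DPYSL4	10
EGFR	10
F13A1	10
FBN2	10
NEFM	10
PTGDS	10
RAB6B	10
RAPGEF4	10
RUNDC3A	10
SERPINA3	10
SH3GL2	10
SNAP25	10
TCEAL2	10
TIMP4	10
LOC101060835	9
ADAM22	9
BCAN	9
C1orf61	9
DDX25	9
ETNPPL	9
FAM107A	9
GABRB1	9
GDF15	9
GNAO1	9
LGI1	9
MEG3	9
NES	9
NPTX2	9
NRXN1	9
NTSR2	9
PEG3	9
PROM1	9
SH3GL3	9
SOX11	9
SPOCK1	9
TMEM35	9
C4B	8
SLC16A3	8
SOD2	8
AIM1	8
ANXA1	8
APOD	8
ATP2B2	8
ATP6V1G2	8
CFI	8
DSP	8
ENPP2	8
FCGBP	8
FUT9	8
FZD6	8
GRB10	8
KDELR3	8
KIF1A	8
LSAMP	8
LYPD1	8
MMP9	8
MYT1L	8
NMNAT2	8
NNAT	8
NOL4	8
NSG1	8
PLBD1	8
RGS1	8
RGS17	8
RGS4	8
RTN1	8
S100A2	8
SLC17A7	8
SRD5A1	8
STC1	8
STEAP3	8
STK32B	8
TAC1	8
VSNL1	8
WIF1	8
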