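TNR
GAD1
TMSB15B
POSTN
SCG3
PLA2G2A
NNMT
CHI3L1
ELAVL4
TF
UGT8
AQP1
COL6A3
ERBB3
KCNQ2
LTF
MEOX2
PCDH9
STMN2
FCGR2B
FGFR3
SLC1A2
CA10
CXCL14
CXorf57
DPYSL4
EGFR
F13A1
FBN2
NEFM
PTGDS
RAB6B
RAPGEF4
RUNDC3A
SERPINA3
SH3GL2
SNAP25
TCEAL2
TIMP4
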