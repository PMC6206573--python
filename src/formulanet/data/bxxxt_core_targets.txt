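ABCA1
ACHE
ADORA1
PARP1
ADRA2C
AHR
AKT1
ALB
AKR1B1
ALOX5
ALOX15
BIRC5
BAX
BCHE
CCND1
BCL2
BDNF
CA1
CA2
CA3
CA4
CA5A
CA6
CA7
CA9
CA12
CASP3
CASP8
CASP9
CAT
CDK1
CDK2
COMT
MAPK14
CSN1S1
CYP1A1
CYP1A2
CYP1B1
CYP2B6
CYP2C19
CYP2C9
CYP2D6
CYP2E1
CYP3A4
CYP19A1
DECR1
NQO1
DRD2
DRD3
DRD4
EGFR
ESR1
ESR2
F3
FASN
FLT3
FOS
GCG
GSK3B
GSTP1
HIF1A
HMGCR
HMOX1
HRH1
HRH2
HTR1A
HTR7
ICAM1
IFNG
IL1B
IL4
IL6
CXCL8
INS
INSR
EIF6
JUN
KCNH1
LCK
LPL
MAOA
MAPT
MMP1
MMP2
MMP9
MPO
ABCC1
NEU2
NFE2L2
NFKB1
NFKBIA
NOS1
NOS2
NOS3
ABCB1
PLA2G1B
PLAU
POLB
PON1
PPARA
PPARD
PPARG
PREP
PRKCA
MAPK1
MAPK3
MAPK8
PTGER3
PTGS1
PTGS2
PTPN1
RB1
RELA
CCL2
SELE
SOD2
SRC
SREBF2
SULT1A1
TH
TNF
TOP2A
TP53
TYR
UROD
VEGFA
XDH
AKR1C3
MGAM
SLCO1B1
CA5B
CA14
SLCO1B3
UGT1A10
UGT1A8
UGT1A7
UGT1A9
UGT1A4
UGT1A1
ABHD6
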