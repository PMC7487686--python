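gene_id	category
ACL4	Ribosome homeostasis
ARB1	Ribosome homeostasis
ARX1	Ribosome homeostasis
BMT5	Ribosome homeostasis
BRX1	Ribosome homeostasis
CBF5	Ribosome homeostasis
DBP10	Ribosome homeostasis
DBP7	Ribosome homeostasis
DBP8	Ribosome homeostasis
DHR2	Ribosome homeostasis
DRS1	Ribosome homeostasis
ECM1	Ribosome homeostasis
EMG1	Ribosome homeostasis
ESF1	Ribosome homeostasis
GAR1	Ribosome homeostasis
GRC3	Ribosome homeostasis
HAS1	Ribosome homeostasis
HPM1	Ribosome homeostasis
IMP3	Ribosome homeostasis
IPI3	Ribosome homeostasis
JIP5	Ribosome homeostasis
KRR1	Ribosome homeostasis
LOC1	Ribosome homeostasis
LSG1	Ribosome homeostasis
MAK11	Ribosome homeostasis
MAK16	Ribosome homeostasis
MRT4	Ribosome homeostasis
NIP7	Ribosome homeostasis
NOP12	Ribosome homeostasis
NOP2	Ribosome homeostasis
NOP4	Ribosome homeostasis
NSR1	Ribosome homeostasis
POP5	Ribosome homeostasis
PUF4	Ribosome homeostasis
PWP1	Ribosome homeostasis
RIX1	Ribosome homeostasis
RIX7	Ribosome homeostasis
RLP24	Ribosome homeostasis
RMT2	Ribosome homeostasis
RPF2	Ribosome homeostasis
RPL15A	Ribosome homeostasis
RPL1A	Ribosome homeostasis
RPL1B	Ribosome homeostasis
RPL24A	Ribosome homeostasis
RPL24B	Ribosome homeostasis
RPL3	Ribosome homeostasis
RPL8B	Ribosome homeostasis
RPL9A	Ribosome homeostasis
RPL9B	Ribosome homeostasis
RPS22A	Ribosome homeostasis
RPS5	Ribosome homeostasis
RPS8B	Ribosome homeostasis
RRB1	Ribosome homeostasis
RRP17	Ribosome homeostasis
SAC3	Ribosome homeostasis
SFM1	Ribosome homeostasis
SPB1	Ribosome homeostasis
SRP40	Ribosome homeostasis
STM1	Ribosome homeostasis
TMA19	Ribosome homeostasis
UTP11	Ribosome homeostasis
UTP14	Ribosome homeostasis
UTP23	Ribosome homeostasis
UTP30	Ribosome homeostasis
UTP5	Ribosome homeostasis
UTP9	Ribosome homeostasis
CDC26	Protein degradation/quality control
CIC1	Protein degradation/quality control
CUZ1	Protein degradation/quality control
ECM29	Protein degradation/quality control
NAS6	Protein degradation/quality control
PRE1	Protein degradation/quality control
PRE10	Protein degradation/quality control
PRE2	Protein degradation/quality control
PRE4	Protein degradation/quality control
PRE9	Protein degradation/quality control
RPN1	Protein degradation/quality control
RPN4	Protein degradation/quality control
RPN5	Protein degradation/quality control
RPN8	Protein degradation/quality control
RPT3	Protein degradation/quality control
RPT4	Protein degradation/quality control
RPT5	Protein degradation/quality control
SCL1	Protein degradation/quality control
SMT3	Protein degradation/quality control
TMC1	Protein degradation/quality control
CCT4	Protein folding/chaperones
CCT7	Protein folding/chaperones
HCH1	Protein folding/chaperones
HSP10	Protein folding/chaperones
PPT1	Protein folding/chaperones
SSA2	Protein folding/chaperones
SSZ1	Protein folding/chaperones
ARF1	Trafficking
GET3	Trafficking
HOT13	Trafficking
HSV2	Trafficking
MLP1	Trafficking
MYO4	Trafficking
NTF2	Trafficking
NUP100	Trafficking
NUP49	Trafficking
PEX4	Trafficking
RET3	Trafficking
SEC22	Trafficking
SEC72	Trafficking
SRM1	Trafficking
SRP21	Trafficking
TOM7	Trafficking
YKT6	Trafficking
YPT31	Trafficking
AAT1	Metabolism
ACS1	Metabolism
ALD6	Metabolism
ARO10	Metabolism
ASP1	Metabolism
CAB5	Metabolism
CAR1	Metabolism
CAT5	Metabolism
COX7	Metabolism
DFR1	Metabolism
DPH2	Metabolism
ECT1	Metabolism
ERG13	Metabolism
ERG9	Metabolism
FAU1	Metabolism
GEP4	Metabolism
GIP4	Metabolism
GUA1	Metabolism
GUK1	Metabolism
MRI1	Metabolism
NPY1	Metabolism
PDC1	Metabolism
PDC5	Metabolism
PRS1	Metabolism
PRS3	Metabolism
PRS5	Metabolism
SAH1	Metabolism
SES1	Metabolism
SFA1	Metabolism
SOL3	Metabolism
SPE3	Metabolism
SUT2	Metabolism
TDA9	Metabolism
URA5	Metabolism
YHR020W	Metabolism
YJU3	Metabolism
CDC33	Transcription, translation
DEF1	Transcription, translation
GCD1	Transcription, translation
HYP2	Transcription, translation
NET1	Transcription, translation
PDP3	Transcription, translation
RPA34	Transcription, translation
RPA49	Transcription, translation
RPB7	Transcription, translation
RPB8	Transcription, translation
RPC31	Transcription, translation
RPC40	Transcription, translation
SLF1	Transcription, translation
SUP35	Transcription, translation
TEF1	Transcription, translation
TFA1	Transcription, translation
TIF2	Transcription, translation
TIF5	Transcription, translation
TOA1	Transcription, translation
ZPR1	Transcription, translation
CWC2	DNA and RNA processing
GCD10	DNA and RNA processing
HRP1	DNA and RNA processing
LHP1	DNA and RNA processing
LSM12	DNA and RNA processing
LSM5	DNA and RNA processing
NAM8	DNA and RNA processing
PAB1	DNA and RNA processing
PAN3	DNA and RNA processing
PRP16	DNA and RNA processing
PRP19	DNA and RNA processing
PRP8	DNA and RNA processing
RRP42	DNA and RNA processing
RRP43	DNA and RNA processing
RSE1	DNA and RNA processing
SEN34	DNA and RNA processing
SET1	DNA and RNA processing
SNU23	DNA and RNA processing
SUB2	DNA and RNA processing
SWD1	DNA and RNA processing
SWM2	DNA and RNA processing
TAD2	DNA and RNA processing
TRM11	DNA and RNA processing
TRM12	DNA and RNA processing
TRM2	DNA and RNA processing
TRM8	DNA and RNA processing
AHC2	Chromosome organization/DNA replication and repair
CBF2	Chromosome organization/DNA replication and repair
DSN1	Chromosome organization/DNA replication and repair
FPR4	Chromosome organization/DNA replication and repair
GSP1	Chromosome organization/DNA replication and repair
MAG1	Chromosome organization/DNA replication and repair
NSE1	Chromosome organization/DNA replication and repair
PAA1	Chromosome organization/DNA replication and repair
POL31	Chromosome organization/DNA replication and repair
RSC4	Chromosome organization/DNA replication and repair
RTT107	Chromosome organization/DNA replication and repair
SGS1	Chromosome organization/DNA replication and repair
TAH11	Chromosome organization/DNA replication and repair
TRA1	Chromosome organization/DNA replication and repair
BUD2	Cell cycle/signaling
CCR4	Cell cycle/signaling
CKA2	Cell cycle/signaling
CLG1	Cell cycle/signaling
CLN3	Cell cycle/signaling
DMA1	Cell cycle/signaling
HST2	Cell cycle/signaling
KIN3	Cell cycle/signaling
KSP1	Cell cycle/signaling
LTE1	Cell cycle/signaling
MAD1	Cell cycle/signaling
NAT5	Cell cycle/signaling
SCH9	Cell cycle/signaling
TOS3	Cell cycle/signaling
TPD3	Cell cycle/signaling
AHP1	Redox homeostasis
GRX3	Redox homeostasis
HMX1	Redox homeostasis
LOT6	Redox homeostasis
MRS4	Redox homeostasis
TAH18	Redox homeostasis
TSA1	Redox homeostasis
YAP1	Redox homeostasis
EMW1	Others
LRE1	Others
OCA5	Others
PTP2	Others
YPD1	Others
AIM29	Putative/unknown function
ANR2	Putative/unknown function
ECL1	Putative/unknown function
GDS1	Putative/unknown function
NRP1	Putative/unknown function
PMU1	Putative/unknown function
RRT14	Putative/unknown function
UBP5	Putative/unknown function
VPS63	Putative/unknown function
YCR043C	Putative/unknown function
YDR222W	Putative/unknown function
YEL068C	Putative/unknown function
YHR138C	Putative/unknown function
YKR011C	Putative/unknown function
YNL010W	Putative/unknown function
YSC83	Putative/unknown function
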