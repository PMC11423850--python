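# Crystallization additives, buffers and cryoprotectants commonly seen in
# deposited structures.  Replaceable: drop in any curated one-ID-per-line
# list (e.g. the full 465-ID additive list) via PipelineConfig.exclusion_path.
GOL
EDO
PEG
PG4
PGE
P6G
1PE
2PE
SO4
PO4
ACT
ACY
DMS
MPD
MRD
TRS
EPE
MES
BME
IPA
IMD
FMT
CIT
FLC
TLA
TAR
MLI
OXL
NO3
SCN
AZI
BCT
CO3
EOH
MOH
BTB
CAC
CHD
NH4
PYR
BOG
LDA
DTT
GSH
SPM
SPD
BEZ
BEN
PHN
DIO
DOX
PDO
BU3
PE4
7PE
XPE
12P
15P
CL
BR
IOD
F
CS
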