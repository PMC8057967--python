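# Example curated driver gene list (well-known cancer genes).
# Placeholder for a user-supplied curated set; one symbol per line.
TP53
KMT2C
CDKN2A
ARID1A
ARID1B
ERBB2
ERBB3
CTNNB1
SMAD4
KRAS
NRAS
HRAS
BRAF
PIK3CA
PTEN
RB1
NF1
NF2
APC
EGFR
MYC
CCND1
FGFR3
FGFR4
NOTCH1
TERT
PTK6
MUTYH
JAK3
STK11
KEAP1
BAP1
PBRM1
IDH1
IDH2
ATM
BRCA1
BRCA2
MLH1
MSH2
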