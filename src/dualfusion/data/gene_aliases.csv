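alias,symbol
ACPP,ACP3
PPAP,ACP3
SEPT14,SEPTIN14
SEPT9,SEPTIN9
C11ORF95,ZFTA
KIAA1549,KIAA1549
CCDC6,CCDC6
PTC,CCDC6
ELE1,NCOA4
TRK,NTRK1
TRKB,NTRK2
TRKC,NTRK3
HGL,NRG1
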