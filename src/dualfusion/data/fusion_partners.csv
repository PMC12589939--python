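driver,partner,chrom
ALK,EML4,chr2
ALK,KIF5B,chr10
ALK,STRN,chr2
RET,KIF5B,chr10
RET,CCDC6,chr10
RET,NCOA4,chr10
ROS1,CD74,chr5
ROS1,SLC34A2,chr4
ROS1,EZR,chr6
NTRK1,TPM3,chr1
NTRK1,LMNA,chr1
NTRK2,AGBL4,chr1
NTRK2,TRIM24,chr7
NTRK3,ETV6,chr12
NTRK3,EML4,chr2
FGFR2,BICC1,chr10
FGFR2,TACC3,chr4
FGFR2,ACP3,chr3
FGFR2,CCDC6,chr10
FGFR3,TACC3,chr4
FGFR3,AES,chr19
NRG1,CD74,chr5
NRG1,ATP1B1,chr1
NRG1,SLC3A2,chr11
NRG1,RBPMS,chr8
NRG1,SDC4,chr20
BRAF,SND1,chr7
BRAF,AGK,chr7
BRAF,KIAA1549,chr7
EGFR,SEPTIN14,chr7
EGFR,VOPP1,chr7
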