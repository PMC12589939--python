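driver,chrom,retained_side,domain_start,domain_end
ALK,chr2,3p,3400,4330
RET,chr10,3p,2350,3160
ROS1,chr6,3p,5900,6700
NTRK1,chr1,3p,1630,2450
NTRK2,chr9,3p,1660,2480
NTRK3,chr15,3p,1640,2470
FGFR2,chr10,5p,1440,2290
FGFR3,chr4,5p,1400,2250
NRG1,chr8,3p,530,710
BRAF,chr7,3p,1370,2120
EGFR,chr7,5p,2110,2920
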