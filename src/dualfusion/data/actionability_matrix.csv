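driver,cancer_type,status
ALK,NSCLC,approved
ROS1,NSCLC,approved
FGFR2,cholangiocarcinoma,approved
FGFR3,bladder,approved
NRG1,NSCLC,approved
NRG1,pancreatic,approved
BRAF,NSCLC,not_approved
BRAF,melanoma,not_approved
EGFR,NSCLC,not_approved
EGFR,glioma,not_approved
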