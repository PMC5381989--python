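gene_id	tags	note
DNAJB5	CVD	Ago 2008
RAC3	lung cancer	Liu 2015
EAPP	lung cancer	DeMuth 1998
HDLBP	CVD	Husten 1998
PRG2	CVD;asthma	Melchior 2013; Li 2006
PER1	CVD	Young 2001
PIK3R1	lung cancer	Lu 2006
SLA2	CVD	Cherpokova 2015
AKAP6	CVD	Oti 2006
LIMK1	lung cancer;Alzheimer	Chen 2013; Heredia 2006
SIRT7	CVD	Vakhrusheva 2008
ARHGAP4	cognition	Huang 2012
ATG16L2	CVD	Magne 2015
TPM3	lung cancer	Rostila 2012
HTR1B	CVD	Iwabayashi 2012
PYGO2	lung cancer	Liu 2013
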