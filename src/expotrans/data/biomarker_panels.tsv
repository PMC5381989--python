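gene_id	sex	disc_fc5	disc_p	val_fc5	val_p	val_q
DNAJB5	M	1.36	0.0014	1.64	0.0026	0.02
RAC3	M	1.25	0.024	1.26	0.10	0.18
EAPP	M	1.15	0.00055	1.18	0.028	0.12
HDLBP	M	1.14	0.0065	1.02	0.75	0.86
PRG2	M	1.29	0.012	1.29	0.066	0.18
PER1	M	1.19	0.012	0.95	0.72	0.86
PIK3R1	M	1.22	0.023	1.01	0.91	0.91
SLA2	M	1.22	0.027	1.16	0.11	0.18
AKAP6	F	1.21	0.0036	0.72	0.017	0.05
LIMK1	F	1.28	0.01	0.75	0.0057	0.03
SIRT7	F	0.89	0.0038	0.80	0.14	0.22
ARHGAP4	F	0.88	0.0035	0.62	0.054	0.11
ATG16L2	F	0.81	0.00028	0.81	0.19	0.25
TPM3	F	0.65	0.0086	1.02	0.85	0.85
HTR1B	F	1.31	0.0097	1.28	0.62	0.71
PYGO2	F	0.93	0.097	0.75	0.0078	0.03
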