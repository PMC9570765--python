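NT	BCUT_PEOE_0	BCUT_PEOE_1	BCUT_PEOE_2	BCUT_PEOE_3	BCUT_SLOGP_0	BCUT_SLOGP_1	BCUT_SLOGP_2	BCUT_SLOGP_3	BCUT_SMR_0	BCUT_SMR_1	BCUT_SMR_2	BCUT_SMR_3
A	-2.08	-0.62	0.72	2.13	-2.32	-0.60	0.76	2.19	-1.75	-0.40	0.96	2.45
C	-2.26	-0.49	0.58	2.21	-2.52	-0.44	0.63	2.10	-1.91	-0.38	0.68	2.54
G	-2.26	-0.66	0.73	2.30	-2.63	-0.60	0.77	2.23	-1.92	-0.49	0.92	2.60
U	-2.30	-0.56	0.55	2.29	-2.61	-0.51	0.66	2.10	-1.97	-0.38	0.69	2.60
T	-2.36	-0.49	0.49	2.37	-2.62	-0.34	0.60	2.34	-2.06	-0.31	0.59	2.66
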