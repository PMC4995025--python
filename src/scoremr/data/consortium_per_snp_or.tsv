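rsid	chrom	pos	effect_allele	other_allele	bcac_eaf	bcac_or	bcac_ci_low	bcac_ci_high	bcac_p	drive_eaf	drive_or	drive_ci_low	drive_ci_high	drive_p	combined_or	combined_ci_low	combined_ci_high	combined_p
rs1558902	16	53803574	A	T	0.41	0.93	0.91	0.95	2.77e-14	0.68	0.95	0.91	0.99	0.008	0.93	0.91	0.95	3.63e-16
rs713586	2	25158008	C	T	0.47	0.94	0.92	0.97	1.82e-06	0.48	0.96	0.93	1.00	0.03	0.95	0.93	0.97	3.19e-07
rs7903146	10	114758349	C	T	0.72	0.96	0.94	0.98	7.01e-05	0.70	0.96	0.92	1.00	0.04	0.96	0.94	0.98	8.65e-06
rs7599312	2	213413231	G	A	0.72	0.96	0.94	0.98	0.0004	0.96	0.94	0.84	1.03	0.17	0.96	0.94	0.98	0.0002
rs17024393	1	110154688	C	T	0.03	0.93	0.87	0.98	0.007	0.41	0.96	0.92	0.99	0.009	0.94	0.91	0.97	0.0003
rs2867125	2	622827	C	T	0.83	0.96	0.94	0.99	0.003	0.64	0.97	0.94	1.00	0.07	0.96	0.94	0.99	0.0008
rs2287019	19	46202172	C	T	0.79	0.96	0.93	0.99	0.009	0.80	0.96	0.92	1.00	0.06	0.96	0.94	0.99	0.0010
rs3810291	19	47569003	A	G	0.67	0.98	0.95	1.00	0.01	0.43	0.96	0.92	0.99	0.01	0.97	0.95	0.99	0.002
rs571312	18	57839769	A	C	0.24	0.97	0.95	1.00	0.02	0.23	0.96	0.92	1.00	0.04	0.97	0.95	0.99	0.002
rs543874	1	177889480	G	A	0.19	0.97	0.95	1.00	0.04	0.20	0.96	0.92	1.00	0.04	0.97	0.95	0.99	0.005
rs12401738	1	78446761	A	G	0.38	0.98	0.96	1.00	0.05	0.38	0.96	0.93	1.00	0.05	0.97	0.96	0.99	0.008
rs1528435	2	181550962	T	C	0.62	0.97	0.95	0.99	0.01	0.63	0.98	0.94	1.01	0.22	0.97	0.96	0.99	0.008
rs2112347	5	75015242	T	G	0.63	0.98	0.96	1.00	0.03	0.44	0.97	0.94	1.00	0.08	0.98	0.96	0.99	0.008
rs10733682	9	129460914	A	G	0.49	0.97	0.95	0.99	0.009	0.47	0.99	0.95	1.02	0.41	0.98	0.96	0.99	0.01
rs13191362	6	163033350	A	G	0.88	1.03	1.00	1.06	0.047	0.87	1.04	0.98	1.09	0.18	1.03	1.01	1.06	0.02
rs17405819	8	76806584	T	C	0.69	0.97	0.95	1.00	0.02	0.69	0.99	0.95	1.02	0.5	0.98	0.96	1.00	0.02
rs3736485	15	51748610	A	G	0.47	0.98	0.96	1.00	0.12	0.43	0.98	0.94	1.01	0.15	0.98	0.96	1.00	0.04
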