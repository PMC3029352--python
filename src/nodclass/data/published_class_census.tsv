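label	n_probes	n_regulators	pct_up	pct_regulators
repressed	1387	97	NA	NA
zone1_2	110	5	5	3
bacA	87	6	NA	NA
fixJ	124	5	NA	NA
diff1	347	27	17	14
diff2	188	12	9	6
fix_plus	159	12	8	6
all_star	95	5	NA	NA
all	172	26	NA	NA
NN	75	8	4	4
exo1	334	62	16	32
exo2	153	10	7	5
N4	10	0	0	0
fix_plus_NN	14	1	1	1
wt_nodules	3	0	0	0
unclear	179	13	9	7
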