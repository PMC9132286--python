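region	start_residue	end_residue	n_residues	mean_rmsf	sd_rmsf
1	28	41	14	4.5	0.5
2	48	70	23	5.1	0.7
3	83	93	11	5.5	0.5
4	201	214	14	4.9	0.2
5	302	307	6	3.5	0.3
6	341	350	10	3.6	0.2
7	549	554	6	3.1	0.2
8	561	569	9	5.0	0.4
9	617	627	11	3.8	0.3
10	642	661	20	4.2	0.3
11	716	726	11	4.9	0.9
12	792	797	6	4.1	0.3
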