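age_group	t1d	t2d	other	total
1-9	822	173	23	1018
10-19	1912	1262	48	3222
20-29	2088	6034	648	8770
30-39	1746	22636	1032	25414
40-49	1377	71492	552	73421
50-59	1214	145947	424	147585
60-69	1226	185581	592	187399
70-79	1433	207022	701	209156
80-89	611	92910	290	93811
90+	61	9798	28	9887
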