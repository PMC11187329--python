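stage	trait	target	f	n_snps	beta	se	ci_low	ci_high	or_value	or_ci_low	or_ci_high	p
control	LDL	ANGPTL3	133.2343	3	0.240	0.130	-0.014	0.495	1.272	0.986	1.641	0.064
control	LDL	APOB	220.249859	19	0.217	0.060	0.101	0.334	1.243	1.106	1.397	<0.001
control	LDL	HMGCR	151.0792208	7	0.368	0.078	0.215	0.520	1.444	1.240	1.682	2.18E-06
control	LDL	LDLR	117.1812478	10	0.599	0.075	0.452	0.746	1.820	1.571	2.108	1.38E-15
control	LDL	NPC1L1	94.5278694	3	0.504	0.164	0.183	0.825	1.655	1.201	2.281	0.002
control	LDL	PCSK9	130.3062592	10	0.421	0.079	0.265	0.576	1.523	1.303	1.779	1.18E-07
control	LDL	PPARA		0								
control	LDL	LPL		0								
control	TG	ANGPTL3	209.4852653	3	0.240	0.130	-0.014	0.495	1.272	0.986	1.641	0.064
control	TG	APOC3	298.7056209	10	0.217	0.055	0.108	0.325	1.242	1.115	1.384	8.74E-05
control	TG	LPL	200.0503049	22	0.428	0.047	0.336	0.519	1.534	1.399	1.681	6.56E-20
control	TG	LDLR		0								
control	TG	PPARA		0								
disease	LDL	HMGCR		7	-0.200	0.355	-0.896	0.497	0.819	0.408	1.644	0.574
disease	LDL	PCSK9		12	0.578	0.233	0.122	1.034	1.782	1.129	2.812	0.013
disease	LDL	NPC1L1		3	-0.651	0.699	-2.020	0.718	0.522	0.133	2.051	0.352
disease	LDL	APOB		20	-0.324	0.226	-0.767	0.118	0.723	0.464	1.126	0.151
disease	LDL	LDLR		14	0.458	0.199	0.069	0.847	1.581	1.071	2.334	0.021
disease	TG	APOC3		10	0.382	0.220	-0.049	0.813	1.465	0.952	2.255	0.083
disease	TG	LPL		24	0.475	0.182	0.117	0.832	1.607	1.124	2.299	0.009
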