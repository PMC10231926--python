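roi	Visual	Somato	SAL	DAN	Limbic	FPCN	DMN
L aInsula	0.00	0.00	65.17	0.00	0.00	24.38	3.09
R aInsula	0.00	0.00	60.02	0.00	0.00	30.59	0.07
R IFJ	0.00	0.00	0.00	79.43	0.00	12.18	0.00
L IPS	4.09	2.80	0.00	39.69	0.00	34.45	4.10
R IPS	6.91	0.00	0.00	55.98	0.00	20.71	0.01
L MFG	0.00	0.48	8.50	18.05	0.00	54.07	1.55
R MFG	0.00	0.00	6.97	0.01	0.00	78.21	0.16
R OFC	0.00	0.00	31.08	0.00	2.94	45.46	2.22
aPCC	0.00	0.00	0.29	0.00	0.00	36.77	20.53
L AG	6.96	0.00	1.11	17.67	0.00	1.65	67.83
R AG	0.43	8.78	7.06	15.91	0.00	0.20	64.95
PCC	5.68	0.00	0.00	0.00	0.00	0.18	88.36
mPFC	0.00	0.00	0.06	0.00	0.06	0.33	91.73
L SFG	0.00	0.00	0.00	0.00	0.00	2.16	80.88
R SFG	0.00	0.43	16.62	0.00	0.00	21.78	36.95
L STG	0.00	45.35	7.34	0.76	0.35	3.63	38.46
R STG	0.10	69.18	5.35	1.77	0.00	1.51	17.58
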