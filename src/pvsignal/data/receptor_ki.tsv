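drug	ror025	D1	D2	D3	5-HT1A	5-HT2A	5-HT2C
clozapine	2.58	240.18	157.55	307.45	139.48	10.30	49.53
olanzapine	2.53	56.93	31.26	38.61	2124.71	4.58	17.86
quetiapine	2.62	1057.85	500.22	386.44	328.25	345.38	2015.50
aripiprazole	2.05	1173.50	2.01	4.60	12.28	32.95	50.34
ziprasidone	3.21	97.28	4.57	7.32	18.44	0.61	3.34
risperidone	1.47	313.44	4.31	6.66	425.26	0.76	28.57
paliperidone	1.53	NA	NA	NA	404.00	0.91	38.00
lurasidone	1.61	NA	1.68	NA	29.90	19.00	481.00
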