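No.	Gene	Position Start	Position End	HSE_seq	Mismatch	Analyzed sequence length
1	TaFes1A-5A	-331	-317	GGCACATTCCAGAAA	CA	2000
2	TaFes1B-4B	-1527	-1513	TTTCTAGCACTTTCT	CA	2000
3	TaFes1C-5A	-19	-5	CATCTCGAAAATTCC	AT	2000
4	TaFes1C-5D	-1985	-1971	GGACCATTCCGGAAC	CA	2000
5	TaFes1A-5A	-4070	-4056	TTACACGAACATTCT	AT	5263 (263)
6	TaFes1A-5A	-594	-580	GGCACATTCCAGAAA	CA	5263 (263)
7	TaFes1A-5B	-2415	-2401	AGAGTTTTCAGGAAG	GA	5274 (274)
8	TaFes1A-5B	-240	-226	CGCAGGTTCCGGAAC	CA	5274 (274)
9	TaFes1A-5D	-233	-219	CGCAGGTTCCGGAAC	CA	3108 (269)
10	TaFes1B-4B	-4738	-4724	ATTCAAGAAAAATCT	AT	5222 (222)
11	TaFes1B-4B	-1749	-1735	TTTCTAGCACTTTCT	CA	5222 (222)
12	TaFes1B-4D	-3759	-3745	TGAATGATCAAGAAC	AT	4741 (0)
13	TaFes1C-5A	-73	-59	CATCTCGAAAATTCC	AT	5054 (54)
14	TaFes1C-5B	-71	-57	CATCTCGAAAATTCC	AT	5076 (76)
15	TaFes1C-5D	-4853	-4839	TTTCATGAAGTATCC	AT	5064 (64)
16	TaFes1C-5D	-2049	-2035	GGACCATTCCGGAAC	CA	5064 (64)
17	TaFes1C-5D	-70	-56	CATCTCGAAAATTCC	AT	5064 (64)
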